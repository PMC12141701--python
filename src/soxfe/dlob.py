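"""Directed Lobish (DLob): symbolic explanations of selected features.

Every DMPat feature indexes a channel pair, and every channel belongs to one
of eight cortical lobes (frontal / occipital / parietal / temporal, left /
right).  Mapping each selected feature's two channels through the montage's
lobe table turns a feature selection into a symbol string of length ``2N``.
The string is summarised three ways: a symbol histogram, its Shannon
entropy, and a transition-count matrix interpretable as a directed cortical
connectome graph (edge weight = number of transitions between two lobes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .dmpat import decode_code
from .errors import MontageError
from .signal_io import LOBE_SYMBOLS, Montage

TRANSITION_MODES = ("consecutive", "per_feature_pair")


@dataclass
class DLobString:
    symbols: tuple[str, ...]
    source_kind: str

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return " ".join(self.symbols)


@dataclass
class ConnectomeMatrix:
    """8x8 transition counts over lobe symbols, indexed (from, to)."""

    counts: np.ndarray
    mode: str

    def total(self) -> int:
        return int(self.counts.sum())


def lobe_table(montage: Montage) -> tuple[str, ...]:
    """The ordered channel-to-lobe lookup of a montage."""
    bad = set(montage.lobe_symbols) - set(LOBE_SYMBOLS)
    if bad:
        raise MontageError(f"unknown lobe symbols {sorted(bad)}")
    return tuple(montage.lobe_symbols)


def feature_index_to_channels(
    index: int, nc: int, source_kind: str = "min_distance"
) -> tuple[int, int]:
    """Map a 1-based feature index to its 1-based channel pair.

    Merged vectors fold: indices ``1..NC**2`` live in the minimum-distance
    code space, ``NC**2+1..2*NC**2`` in the maximum-distance space; the
    channel decoding is identical in both.
    """
    n_sq = nc * nc
    upper = 2 * n_sq if source_kind == "merged" else n_sq
    if not 1 <= index <= upper:
        raise ValueError(f"feature index {index} out of range 1..{upper}")
    if index > n_sq:
        index -= n_sq
    return decode_code(index - 1, nc)


def build_dlob_string(
    chosen_indices: Sequence[int],
    montage: Montage,
    source_kind: str = "min_distance",
    *,
    zero_based: bool = True,
) -> DLobString:
    """Two lobe symbols per selected feature, in selection order.

    ``chosen_indices`` are 0-based feature-column indices by default (as a
    selection result stores them); set ``zero_based=False`` for 1-based.
    """
    table = lobe_table(montage)
    symbols: list[str] = []
    for idx in chosen_indices:
        one_based = int(idx) + 1 if zero_based else int(idx)
        ch1, ch2 = feature_index_to_channels(one_based, montage.n_channels, source_kind)
        symbols.append(table[ch1 - 1])
        symbols.append(table[ch2 - 1])
    return DLobString(symbols=tuple(symbols), source_kind=source_kind)


def symbol_histogram(dls: DLobString | Sequence[str]) -> dict[str, int]:
    """Occurrences of each of the eight lobe symbols."""
    symbols = dls.symbols if isinstance(dls, DLobString) else tuple(dls)
    counts = {s: 0 for s in LOBE_SYMBOLS}
    for s in symbols:
        if s not in counts:
            raise ValueError(f"unknown symbol {s!r}")
        counts[s] += 1
    return counts


def shannon_entropy(dls: DLobString | Sequence[str], base: float = 2) -> float:
    """Shannon entropy of the observed symbol frequencies (bits by default)."""
    symbols = dls.symbols if isinstance(dls, DLobString) else tuple(dls)
    if len(symbols) == 0:
        raise ValueError("entropy of an empty string is undefined")
    counts = np.array([c for c in symbol_histogram(symbols).values() if c > 0])
    return float(_scipy_entropy(counts, base=base))


def transition_matrix(
    dls: DLobString | Sequence[str], mode: str = "consecutive"
) -> ConnectomeMatrix:
    """Count symbol transitions.

    ``consecutive`` counts every adjacent pair of the string (total =
    length - 1); ``per_feature_pair`` counts only within-feature transitions
    at positions (1,2), (3,4), ... (total = N features).
    """
    symbols = dls.symbols if isinstance(dls, DLobString) else tuple(dls)
    if len(symbols) < 2:
        raise ValueError("need at least 2 symbols for transitions")
    if mode not in TRANSITION_MODES:
        raise ValueError(f"unknown transition mode {mode!r}")
    pos = {s: i for i, s in enumerate(LOBE_SYMBOLS)}
    counts = np.zeros((8, 8), dtype=int)
    if mode == "consecutive":
        pairs = zip(symbols[:-1], symbols[1:])
    else:
        pairs = zip(symbols[0::2], symbols[1::2])
    for a, b in pairs:
        counts[pos[a], pos[b]] += 1
    return ConnectomeMatrix(counts=counts, mode=mode)


def connectome_graph(cm: ConnectomeMatrix) -> nx.DiGraph:
    """Directed weighted graph over lobe symbols; zero-count edges omitted."""
    g = nx.DiGraph(mode=cm.mode)
    g.add_nodes_from(LOBE_SYMBOLS)
    for i, a in enumerate(LOBE_SYMBOLS):
        for j, b in enumerate(LOBE_SYMBOLS):
            w = int(cm.counts[i, j])
            if w > 0:
                g.add_edge(a, b, weight=w)
    return g


def export_connectome(cm: ConnectomeMatrix, path: str | Path, format: str = "graphml") -> None:
    """Write the connectome graph as GraphML, DOT, or a JSON edge list."""
    path = Path(path)
    g = connectome_graph(cm)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph connectome {"]
        for a, b, data in g.edges(data=True):
            lines.append(f'  {a} -> {b} [label="{data["weight"]}", weight={data["weight"]}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "mode": cm.mode,
            "nodes": list(LOBE_SYMBOLS),
            "edges": [
                {"from": a, "to": b, "count": int(d["weight"])}
                for a, b, d in g.edges(data=True)
            ],
        }
        path.write_text(json.dumps(payload, sort_keys=True, indent=2))
    else:
        raise ValueError(f"unknown export format {format!r}")


def dlob_report(
    chosen_indices: Sequence[int],
    montage: Montage,
    source_kind: str,
    *,
    entropy_base: float = 2,
    transition_mode: str = "consecutive",
) -> dict:
    """JSON-ready summary: string, histogram, entropy, transition counts."""
    dls = build_dlob_string(chosen_indices, montage, source_kind)
    cm = transition_matrix(dls, transition_mode) if len(dls) >= 2 else None
    return {
        "source_kind": source_kind,
        "string": list(dls.symbols),
        "length": len(dls),
        "histogram": symbol_histogram(dls),
        "entropy": shannon_entropy(dls, base=entropy_base) if len(dls) else None,
        "entropy_base": entropy_base,
        "transition_mode": transition_mode,
        "transitions": cm.counts.tolist() if cm is not None else None,
    }
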
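"""Distance-matrix pattern (DMPat) feature extraction.

For every time sample the instantaneous amplitudes of all ``NC`` channels are
compared pairwise with the radial distance ``sqrt(ch_i^2 + ch_j^2)``.  The
channel pair attaining the minimum distance and the pair attaining the
maximum distance are each encoded as a single integer code

    val = (a1 - 1) * NC + (a2 - 1)        (channels 1-based, code 0-based)

so a segment of ``L`` samples yields two code sequences of length ``L``.
Histogramming the codes over all ``NC**2`` possible values gives two count
feature vectors ``f1`` (minimum-distance pairs) and ``f2`` (maximum-distance
pairs); their concatenation ``f3`` is the merged vector of length
``2 * NC**2``.

Conventions (the distance matrix is symmetric, so these must be fixed):

* only unordered pairs with ``a1 < a2`` compete — the diagonal, which would
  compare a channel with itself, is excluded;
* ties are broken by the first pair in row-major scan order of the upper
  triangle, so codes are deterministic;
* histograms are raw counts, not normalised.

Because argmin/argmax of a monotone function of amplitudes is invariant to
positive rescaling, the codes depend only on the relative amplitude structure
across channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError
from .signal_io import Segment

FEATURE_KINDS = ("min_distance", "max_distance", "merged")


@dataclass
class PairCodeSequence:
    """Per-sample integer codes of the extreme-distance channel pairs."""

    codes_min: np.ndarray
    codes_max: np.ndarray
    nc: int


@dataclass
class FeatureVector:
    """Histogram of pair codes; ``kind`` records which code stream it counts."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.int64)


def pair_distance(ch_i: float, ch_j: float) -> float:
    """Radial distance between two instantaneous channel amplitudes."""
    if not (np.isfinite(ch_i) and np.isfinite(ch_j)):
        raise ValueError("channel amplitudes must be finite")
    return float(np.hypot(ch_i, ch_j))


def encode_sample(column: Sequence[float]) -> tuple[int, int]:
    """Encode one time sample: codes of the min- and max-distance pairs."""
    col = np.asarray(column, dtype=float)
    nc = col.shape[0]
    if nc < 2:
        raise DimensionError("need at least 2 channels to form a pair")
    if not np.all(np.isfinite(col)):
        raise ValueError("channel amplitudes must be finite")
    iu, ju = np.triu_indices(nc, k=1)
    # sqrt is monotone: compare squared sums, same argmin/argmax and ties
    pair_sums = col[iu] ** 2 + col[ju] ** 2
    lo = int(np.argmin(pair_sums))
    hi = int(np.argmax(pair_sums))
    val_min = int(iu[lo]) * nc + int(ju[lo])
    val_max = int(iu[hi]) * nc + int(ju[hi])
    return val_min, val_max


def decode_code(val: int, nc: int) -> tuple[int, int]:
    """Invert the pair code into 1-based channel indices ``(a1, a2)``."""
    if not 0 <= val <= nc * nc - 1:
        raise ValueError(f"code {val} out of range for {nc} channels")
    return val // nc + 1, val % nc + 1


def encode_segment(segment: Segment | np.ndarray) -> PairCodeSequence:
    """Encode every sample column of a segment independently."""
    signal = segment.signal if isinstance(segment, Segment) else np.asarray(segment, float)
    if signal.ndim != 2:
        raise DimensionError("segment signal must be 2-D (channels x samples)")
    nc = signal.shape[0]
    if nc < 2:
        raise DimensionError("need at least 2 channels")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    iu, ju = np.triu_indices(nc, k=1)
    sq = signal ** 2
    pair_sums = sq[iu] + sq[ju]  # (n_pairs, L)
    lo = np.argmin(pair_sums, axis=0)  # first occurrence wins ties
    hi = np.argmax(pair_sums, axis=0)
    codes_min = iu[lo] * nc + ju[lo]
    codes_max = iu[hi] * nc + ju[hi]
    return PairCodeSequence(codes_min=codes_min, codes_max=codes_max, nc=nc)


def histogram_features(codes: PairCodeSequence) -> tuple[FeatureVector, FeatureVector]:
    """Raw-count histograms of the two code streams over all ``NC**2`` bins."""
    n_bins = codes.nc ** 2
    f1 = np.bincount(codes.codes_min, minlength=n_bins)
    f2 = np.bincount(codes.codes_max, minlength=n_bins)
    return (
        FeatureVector(values=f1, kind="min_distance"),
        FeatureVector(values=f2, kind="max_distance"),
    )


def merge_features(f1: FeatureVector, f2: FeatureVector) -> FeatureVector:
    """Concatenate the min- and max-distance histograms."""
    if f1.values.shape != f2.values.shape:
        raise DimensionError("feature vectors to merge must have equal length")
    return FeatureVector(values=np.concatenate([f1.values, f2.values]), kind="merged")


def extract_all(
    segments: Iterable[Segment | np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract the three feature matrices for a sequence of segments.

    Returns ``(F1, F2, F3)`` with shapes ``(n, NC**2)``, ``(n, NC**2)`` and
    ``(n, 2*NC**2)``; row order follows segment order.
    """
    rows1, rows2, rows3 = [], [], []
    nc_seen = None
    for seg in segments:
        codes = encode_segment(seg)
        if nc_seen is None:
            nc_seen = codes.nc
        elif codes.nc != nc_seen:
            raise DimensionError("segments have inconsistent channel counts")
        f1, f2 = histogram_features(codes)
        f3 = merge_features(f1, f2)
        rows1.append(f1.values)
        rows2.append(f2.values)
        rows3.append(f3.values)
    if not rows1:
        raise DimensionError("need at least one segment")
    return np.array(rows1), np.array(rows2), np.array(rows3)


def _bin_names(nc: int, kind: str) -> list[str]:
    if kind == "merged":
        return _bin_names(nc, "min_distance") + _bin_names(nc, "max_distance")
    prefix = "min" if kind == "min_distance" else "max"
    return [f"{prefix}_{i:03d}" for i in range(nc * nc)]


def write_feature_matrix(matrix: np.ndarray, nc: int, kind: str, path: str | Path) -> None:
    """Write a feature matrix as a delimited table with named bin columns."""
    pd.DataFrame(matrix, columns=_bin_names(nc, kind)).to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int64)
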
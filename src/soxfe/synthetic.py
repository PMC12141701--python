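"""Synthetic two-class multichannel EEG with planted channel-pair structure.

The generator emulates the structure of a two-class EEG study — multiple
records per class, each split into fixed 15-s windows at 128 Hz over a
14-channel montage — with the minimal signal the distance-pattern extractor
is sensitive to: per-channel amplitude structure.  Each channel carries
AR(1)-correlated Gaussian noise scaled by a class-specific gain profile.
Suppressing a different channel pair per class (x0.1 by default: channels
1-2 for class 1, channels 7-8 for class 2) forces the minimum-distance
argmin onto different pairs, so the classes are separable in the pattern
histograms while individual samples remain noisy.

No oscillatory (band-limited, 1/f) content or artifacts are simulated; the
generator provides a controlled learnability test, not physiological EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import Montage, EEGRecord


def _default_profiles() -> dict[int, np.ndarray]:
    g1 = np.ones(14)
    g1[[0, 1]] = 0.1  # class 1 suppresses channels 1-2 (AF3, F7)
    g2 = np.ones(14)
    g2[[6, 7]] = 0.1  # class 2 suppresses channels 7-8 (O1, O2)
    return {1: g1, 2: g2}


@dataclass
class SynthConfig:
    """Study-shaped defaults: 14 channels at 128 Hz, 15-s windows,
    10 records per class with 4 windows each, AR(1) noise."""

    nc: int = 14
    fs: float = 128.0
    window_seconds: float = 15.0
    records_per_class: int = 10
    segments_per_record: int = 4
    class_gain_profiles: dict[int, np.ndarray] = field(default_factory=_default_profiles)
    noise_sd: float = 1.0
    ar_coefficient: float = 0.9
    seed: int = 0

    def null_variant(self) -> "SynthConfig":
        """Same sizes, identical gain profiles: an unlearnable null dataset."""
        flat = {c: np.ones(self.nc) for c in self.class_gain_profiles}
        return replace(self, class_gain_profiles=flat)

    def validate(self) -> None:
        if self.nc < 2 or self.fs <= 0 or self.window_seconds <= 0:
            raise ValueError("degenerate signal geometry")
        if self.records_per_class < 1 or self.segments_per_record < 1:
            raise ValueError("need at least one record and one segment")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for c, g in self.class_gain_profiles.items():
            g = np.asarray(g)
            if g.shape != (self.nc,) or np.any(g <= 0):
                raise ValueError(f"gain profile for class {c} must be {self.nc} positive values")


def generate_dataset(cfg: SynthConfig) -> list[EEGRecord]:
    """Generate the full record list; byte-identical for a given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    window = int(round(cfg.fs * cfg.window_seconds))
    n_samples = window * cfg.segments_per_record
    records: list[EEGRecord] = []
    for label in sorted(cfg.class_gain_profiles):
        gains = np.asarray(cfg.class_gain_profiles[label], dtype=float)
        for r in range(cfg.records_per_class):
            noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.nc, n_samples))
            signal = np.empty_like(noise)
            signal[:, 0] = noise[:, 0]
            a = cfg.ar_coefficient
            for t in range(1, n_samples):
                signal[:, t] = a * signal[:, t - 1] + noise[:, t]
            signal *= gains[:, None]
            records.append(
                EEGRecord(
                    record_id=f"rec_c{label}_{r:03d}",
                    label=int(label),
                    signal=signal,
                    fs=cfg.fs,
                )
            )
    return records


def write_dataset(
    records: list[EEGRecord], out_dir: str | Path, montage: Montage | None = None
) -> Path:
    """Write one CSV per record plus a ``manifest.csv``; returns the manifest
    path.  Files are channels-in-rows delimited matrices readable by the
    signal loader."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.record_id}.csv"
        np.savetxt(out_dir / fname, rec.signal, delimiter=",", fmt="%.6f")
        rows.append({"path": fname, "record_id": rec.record_id, "label": rec.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
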
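"""Reading multichannel EEG records and splitting them into fixed windows.

A :class:`Montage` names the channels (in order) and assigns each a brain-lobe
symbol used by the explainability layer.  Records are validated against the
montage on load and reordered to montage channel order when the source format
carries channel names.  Segmentation is non-overlapping: consecutive windows
of exactly ``fs * window_seconds`` samples, with any trailing remainder
shorter than one window discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, MontageError

#: The eight brain-lobe symbols: frontal/occipital/parietal/temporal, left/right.
LOBE_SYMBOLS = ("FL", "FR", "OL", "OR", "PL", "PR", "TL", "TR")

#: 14-channel consumer EEG headset layout (10-20 positions) with its
#: channel-to-lobe assignment.
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)
DEFAULT_LOBES = (
    "FL", "FL", "FL", "FL", "TL", "PL", "OL",
    "OR", "PR", "TR", "FR", "FR", "FR", "FR",
)


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus one lobe symbol per channel."""

    channel_names: tuple[str, ...]
    lobe_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.channel_names) != len(self.lobe_symbols):
            raise MontageError(
                f"{len(self.channel_names)} channel names but "
                f"{len(self.lobe_symbols)} lobe symbols"
            )
        bad = set(self.lobe_symbols) - set(LOBE_SYMBOLS)
        if bad:
            raise MontageError(f"unknown lobe symbols: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @classmethod
    def default_14_channel(cls) -> "Montage":
        return cls(DEFAULT_CHANNELS, DEFAULT_LOBES)


@dataclass
class EEGRecord:
    """One full recording session: an ``NC x S`` signal with a class label."""

    record_id: str
    label: int
    signal: np.ndarray  # shape (NC, S)
    fs: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise DimensionError("signal must be a 2-D channels x samples matrix")
        if self.signal.shape[0] < 2 or self.signal.shape[1] < 1:
            raise DimensionError("need at least 2 channels and 1 sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class Segment:
    """A fixed-length window cut from a record; inherits its label and id."""

    parent_record_id: str
    label: int
    signal: np.ndarray  # shape (NC, L)


def _validate_against_montage(
    signal: np.ndarray,
    montage: Montage,
    channel_names: Sequence[str] | None,
) -> np.ndarray:
    """Reorder rows to montage order by name, or accept by position."""
    if signal.shape[0] != montage.n_channels:
        raise MontageError(
            f"file has {signal.shape[0]} channels, montage expects "
            f"{montage.n_channels}"
        )
    if channel_names is None:
        return signal
    names = [str(n).strip() for n in channel_names]
    lookup = {n.upper(): i for i, n in enumerate(names)}
    try:
        order = [lookup[n.upper()] for n in montage.channel_names]
    except KeyError as exc:
        raise MontageError(f"channel {exc} missing from file") from exc
    return signal[order]


def _read_delimited(
    path: Path, channels_in_rows: bool, delimiter: str | None
) -> tuple[np.ndarray, list[str] | None]:
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            engine="python" if delimiter is None else "c",
            header=None,
        )
    except Exception as exc:  # pragma: no cover - pandas error detail varies
        raise FormatError(f"cannot parse delimited file {path}: {exc}") from exc
    names: list[str] | None = None
    first_row = df.iloc[0]
    if first_row.map(lambda v: isinstance(v, str)).any():
        # header row carries channel names
        header_axis_names = [str(v) for v in first_row]
        df = df.iloc[1:].reset_index(drop=True)
        if channels_in_rows:
            # names label columns => data is samples x channels on disk
            names = header_axis_names
            mat = df.to_numpy(dtype=float).T
            return mat, names
        names = header_axis_names
        mat = df.to_numpy(dtype=float).T  # columns are channels
        return mat, names
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric data in {path}") from exc
    if not channels_in_rows:
        mat = mat.T
    return mat, names


def _read_edf(path: Path) -> tuple[np.ndarray, list[str], float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF support requires the optional 'mne' dependency") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])


def _read_matlab(path: Path, key: str | None) -> np.ndarray:
    """Read a 2-D numeric variable from a classic or v7.3 (HDF5) container."""
    import scipy.io

    try:
        contents = scipy.io.loadmat(path)
        arrays = {
            k: np.asarray(v)
            for k, v in contents.items()
            if not k.startswith("__") and np.asarray(v).ndim == 2
        }
    except (NotImplementedError, ValueError):
        # v7.3 containers are HDF5 files; scipy punts on them
        import h5py

        arrays = {}
        try:
            with h5py.File(path, "r") as f:
                for k in f:
                    v = f[k]
                    if hasattr(v, "shape") and len(v.shape) == 2:
                        # HDF5 MATLAB containers store arrays transposed
                        arrays[k] = np.asarray(v).T
        except OSError as exc:
            raise FormatError(f"cannot read MATLAB container {path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"cannot read MATLAB container {path}: {exc}") from exc
    if not arrays:
        raise FormatError(f"no 2-D numeric variable found in {path}")
    if key is not None:
        if key not in arrays:
            raise FormatError(f"variable {key!r} not found in {path}")
        return arrays[key].astype(float)
    first = next(iter(arrays))
    return arrays[first].astype(float)


def load_record(
    path: str | Path,
    format: str,
    montage: Montage,
    label: int,
    record_id: str,
    *,
    fs: float = 128.0,
    channels_in_rows: bool = True,
    delimiter: str | None = None,
    mat_key: str | None = None,
) -> EEGRecord:
    """Load one EEG record and validate it against the montage.

    ``format`` is one of ``edf``, ``delimited``, ``matlab-container``.  For
    EDF, the file's own sampling rate and channel names are used and rows are
    reordered to montage order; the other formats are raw matrices taken in
    positional channel order (``channels_in_rows`` selects the on-disk
    orientation for delimited files).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    names: Sequence[str] | None = None
    if format == "edf":
        signal, names, fs = _read_edf(path)
    elif format == "delimited":
        signal, names = _read_delimited(path, channels_in_rows, delimiter)
    elif format == "matlab-container":
        signal = _read_matlab(path, mat_key)
        if signal.shape[0] != montage.n_channels and signal.shape[1] == montage.n_channels:
            signal = signal.T
    else:
        raise FormatError(f"unknown format {format!r}")
    signal = _validate_against_montage(np.asarray(signal, float), montage, names)
    return EEGRecord(record_id=record_id, label=int(label), signal=signal, fs=fs)


def segment_record(record: EEGRecord, window_seconds: float) -> list[Segment]:
    """Cut a record into consecutive non-overlapping windows of
    ``fs * window_seconds`` samples; a trailing remainder is dropped."""
    length = record.fs * window_seconds
    if length <= 0 or abs(length - round(length)) > 1e-9:
        raise ValueError(
            f"window of {window_seconds} s at {record.fs} Hz is not a whole "
            "number of samples"
        )
    length = int(round(length))
    n_windows = record.n_samples // length
    if n_windows == 0:
        warnings.warn(
            f"record {record.record_id} shorter than one window; no segments",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            parent_record_id=record.record_id,
            label=record.label,
            signal=record.signal[:, i * length:(i + 1) * length].copy(),
        )
        for i in range(n_windows)
    ]


@dataclass
class Dataset:
    """Segments plus their labels and parent-record ids, pipeline-ready."""

    segments: list[Segment] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments])

    @property
    def record_ids(self) -> list[str]:
        return [s.parent_record_id for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)


def load_manifest(
    manifest_path: str | Path,
    montage: Montage,
    *,
    format: str = "delimited",
    fs: float = 128.0,
    window_seconds: float = 15.0,
    **load_kwargs,
) -> Dataset:
    """Load and segment every record listed in a manifest table.

    The manifest is a delimited file with columns ``path``, ``record_id``,
    ``label``; relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path)
    missing = {"path", "record_id", "label"} - set(table.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    dataset = Dataset()
    for row in table.itertuples(index=False):
        rec_path = Path(row.path)
        if not rec_path.is_absolute():
            rec_path = manifest_path.parent / rec_path
        record = load_record(
            rec_path, format, montage, label=row.label,
            record_id=str(row.record_id), fs=fs, **load_kwargs,
        )
        dataset.segments.extend(segment_record(record, window_seconds))
    return dataset
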
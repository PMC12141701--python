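"""Exception hierarchy shared across the pipeline stages."""


class SoxfeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SoxfeError):
    """A file could not be read in the requested format."""


class MontageError(SoxfeError):
    """Channel layout does not reconcile with the montage."""


class DimensionError(SoxfeError):
    """Array shapes are inconsistent with the operation's contract."""


class PartitionError(SoxfeError):
    """A cross-validation partition is degenerate (empty fold, single record)."""


class DegenerateLabelsError(SoxfeError):
    """Labels contain fewer than two classes."""
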
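import numpy as np
import pytest

from soxfe import (
    Dataset,
    Montage,
    SynthConfig,
    generate_dataset,
    segment_record,
)


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage.default_14_channel()


def segmented(cfg: SynthConfig) -> Dataset:
    records = generate_dataset(cfg)
    return Dataset(
        [s for r in records for s in segment_record(r, cfg.window_seconds)]
    )


@pytest.fixture(scope="session")
def small_planted() -> Dataset:
    """Planted-pair dataset small enough for per-module tests."""
    return segmented(SynthConfig(records_per_class=5, segments_per_record=2, seed=7))


@pytest.fixture(scope="session")
def default_planted() -> Dataset:
    """The generator's default study-shaped planted dataset."""
    return segmented(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_null() -> Dataset:
    return segmented(SynthConfig(seed=1).null_variant())


def make_separable(n: int = 60, p: int = 8, seed: int = 0, gap: float = 6.0):
    """Two Gaussian clusters separated along the first two features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 2], n // 2)
    x = rng.normal(size=(n, p))
    x[y == 1, :2] += gap
    return x, y
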
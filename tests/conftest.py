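import numpy as np
import pytest

from pinpool import MatrixLayout, VariantKey


def vk(pos: int, ref: str = "A", alt: str = "G", chrom: str = "chr1") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)


def int_keys(ids) -> set:
    """Abstract variants for pure set-algebra tests: one SNV per integer id."""
    return {VariantKey("chr1", 10 * i + 1, "A", "G") for i in ids}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def grid_3x3():
    return MatrixLayout.full_grid(3, 3)


def random_cohort(rng, n_samples: int, n_variants: int, carry_prob: float = 0.3):
    """Random per-sample variant sets over a shared pool of keys."""
    keys = sorted(int_keys(range(n_variants)))
    samples = [f"S{i}" for i in range(n_samples)]
    return {
        s: {k for k in keys if rng.random() < carry_prob} for s in samples
    }
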
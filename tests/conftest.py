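import numpy as np
import pytest

from plasmodeval import BaseSimDesign, CountMatrix, SampleMeta, simulate_base_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 samples with hand-computable size factors (0.5, 2)."""
    return CountMatrix(["g1", "g2", "g3"], ["s1", "s2"],
                       np.array([[2, 8], [4, 16], [8, 32]]))


@pytest.fixture
def small_nb():
    """Seeded NB matrix with two groups, one block; no true DE."""
    design = BaseSimDesign(n_genes=300,
                           samples=[("A", "b1")] * 4 + [("B", "b1")] * 4,
                           frac_de=0.0, block_lfc_sd=0.0, seed=42)
    cm, meta, _ = simulate_base_counts(design)
    return cm.drop_all_zero(), meta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
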
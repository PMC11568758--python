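import numpy as np
import pytest

from clinesel.haplotypes import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_panel(alleles, bp_spacing=1000, cm_per_mb=1.0):
    """Panel with uniform physical spacing and a uniform genetic map."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites = alleles.shape[1]
    bp = 1 + np.arange(n_sites, dtype=np.int64) * bp_spacing
    return HaplotypePanel(
        alleles=alleles, positions_bp=bp, positions_cm=bp * 1e-6 * cm_per_mb
    )


@pytest.fixture
def random_panel(rng):
    """16 haplotypes x 12 polymorphic sites, complete data."""
    while True:
        alleles = rng.integers(0, 2, size=(16, 12)).astype(np.int8)
        freqs = alleles.mean(axis=0)
        if ((freqs > 0) & (freqs < 1)).all():
            return make_panel(alleles)
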
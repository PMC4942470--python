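import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gmanova import GenotypeDataset, Locus
from gmanova.coding import pair_indices

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_locus(m: int, name: str = "L1", freqs=None) -> Locus:
    return Locus(
        name=name,
        alleles=[str(i) for i in range(m)],
        freqs=None if freqs is None else np.asarray(freqs, float),
        ref_allele=str(m - 1),
    )


def complete_random_dataset(rng, ms, n=None, sigma=1.0):
    """Random dataset with every genotype cell occupied and a random phenotype."""
    loci = [make_locus(m, name=f"L{i + 1}") for i, m in enumerate(ms)]
    if len(ms) == 1:
        cells = [(c,) for c in pair_indices(ms[0])]
    else:
        cells = [(c1, c2) for c1 in pair_indices(ms[0]) for c2 in pair_indices(ms[1])]
    n = max(n or 0, 3 * len(cells))
    idx = np.concatenate([np.arange(len(cells)), rng.integers(0, len(cells), n - len(cells))])
    genotypes = [np.array([cells[i][loc] for i in idx]) for loc in range(len(ms))]
    y = rng.normal(0.0, sigma, size=n) + rng.normal(0.0, 1.0, size=len(cells))[idx]
    return GenotypeDataset(loci=loci, genotypes=genotypes, phenotype=y)


def random_simplex(rng, m, floor=0.05):
    p = rng.dirichlet(np.ones(m) * 5.0)
    p = np.maximum(p, floor)
    return p / p.sum()
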
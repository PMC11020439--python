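import numpy as np
import pytest

from msatpop.panel import GenotypePanel, Individual, Locus


def make_panel(genotypes, sections=None, motif=4, seasons=None, years=None, locus_names=None):
    """Build a panel from a (n, L, 2) nested list of allele sizes (-1 = missing)."""
    calls = np.asarray(genotypes, dtype=np.int32)
    if calls.ndim == 2:
        calls = calls[:, None, :]
    n, L, _ = calls.shape
    sections = sections or ["pop1"] * n
    seasons = seasons or ["unknown"] * n
    years = years or [None] * n
    names = locus_names or [f"loc{j + 1}" for j in range(L)]
    inds = [
        Individual(f"ind{i:03d}", sections[i], seasons[i], years[i]) for i in range(n)
    ]
    return GenotypePanel([Locus(nm, motif) for nm in names], inds, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def hw_panel_factory():
    """Panels of HWE genotypes at given allele frequencies (single population)."""

    def build(freqs_per_locus, n, seed=0, sections=None):
        rng = np.random.default_rng(seed)
        L = len(freqs_per_locus)
        calls = np.zeros((n, L, 2), dtype=np.int32)
        for j, p in enumerate(freqs_per_locus):
            p = np.asarray(p, dtype=float)
            p = p / p.sum()
            calls[:, j, :] = 100 + 4 * rng.choice(len(p), size=(n, 2), p=p)
        return make_panel(calls, sections=sections)

    return build


@pytest.fixture
def two_pop_panel_factory():
    """Two populations with specified allele frequencies at one locus."""

    def build(p1, p2, n1, n2, seed=0):
        rng = np.random.default_rng(seed)
        p1 = np.asarray(p1) / np.sum(p1)
        p2 = np.asarray(p2) / np.sum(p2)
        k = len(p1)
        g1 = 100 + 4 * rng.choice(k, size=(n1, 2), p=p1)
        g2 = 100 + 4 * rng.choice(k, size=(n2, 2), p=p2)
        calls = np.concatenate([g1, g2])[:, None, :]
        return make_panel(calls, sections=["P1"] * n1 + ["P2"] * n2)

    return build
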
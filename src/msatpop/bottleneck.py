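"""Heterozygosity-excess bottleneck tests and the Garza-Williamson M-ratio.

After a recent crash, rare alleles are lost faster than heterozygosity, so the
observed gene diversity exceeds the equilibrium value expected for the
observed allele number.  The equilibrium distribution of heterozygosity given
the sample size and allele count is obtained by coalescent simulation under
IAM, SMM or TPM mutation (the Cornuet-Luikart procedure): theta is chosen so
the expected allele number matches the observed one, and only replicates that
realize exactly that allele number are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diversity import _pop_indices
from .panel import GenotypePanel

__all__ = [
    "MutationModel",
    "BottleneckReport",
    "simulate_heq",
    "heterozygosity_excess_test",
    "m_ratio",
    "m_ratio_mean",
    "wilcoxon_one_tailed",
]

IAM = "IAM"
SMM = "SMM"
TPM = "TPM"


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite mutation model: IAM, strict stepwise, or two-phase.

    TPM defaults follow the BOTTLENECK program convention: 70% single-step
    mutations with a multi-step geometric component of variance 30.
    """

    kind: str = TPM
    p_single_step: float = 0.70
    multistep_variance: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in (IAM, SMM, TPM):
            raise ValueError(f"unknown mutation model {self.kind!r}")
        if not 0.0 <= self.p_single_step <= 1.0:
            raise ValueError("p_single_step must be in [0, 1]")
        if self.multistep_variance <= 0:
            raise ValueError("multistep_variance must be positive")


@dataclass
class LocusExcess:
    locus: str
    he_observed: float
    heq_mean: float
    heq_sd: float
    dh: float


@dataclass
class BottleneckReport:
    population: str
    p_iam: float | None = None
    p_smm: float | None = None
    p_tpm: float | None = None
    per_locus: dict[str, list[LocusExcess]] = field(default_factory=dict)
    m_ratio: float | None = None
    m_below_criterion: bool | None = None
    n_sim: int = 0


# ------------------------------------------------------------- coalescent Heq
def _coalescent_leaf_states(n: int, theta: float, model: MutationModel, rng: np.random.Generator) -> np.ndarray:
    """One coalescent genealogy of n genes with mutations; returns leaf allele states."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1 = int(rng.integers(j))
        i2 = int(rng.integers(j - 1))
        if i2 >= i1:
            i2 += 1
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        # remove the two merged lineages, append the new one
        for x in sorted((i1, i2), reverse=True):
            active[x] = active[-1]
            active.pop()
        active.append(nxt)
        nxt += 1
    root = n_nodes - 1
    branch = time[parent[:root]] - time[:root]  # branch length above each non-root node
    total = float(branch.sum())
    states = np.zeros(n_nodes, dtype=np.int64)
    n_mut = rng.poisson(theta / 2.0 * total) if total > 0 else 0
    if n_mut == 0:
        return states[:n]
    mut_count = rng.multinomial(n_mut, branch / total)
    if model.kind == IAM:
        # only the most recent mutation on the path to a leaf matters; a
        # mutated branch relabels everything below it with a fresh allele
        mutated = mut_count > 0
        for node in range(n_nodes - 2, -1, -1):
            states[node] = node + 1 if mutated[node] else states[parent[node]]
        return states[:n]
    # stepwise models: only the net repeat-count displacement per branch matters
    if model.kind == SMM:
        net = 2 * rng.binomial(mut_count, 0.5) - mut_count
    else:  # TPM: mixture of single steps and geometric multi-steps
        v = model.multistep_variance
        q_geom = (-1.0 + math.sqrt(1.0 + 4.0 * v)) / (2.0 * v)
        singles = rng.binomial(mut_count, model.p_single_step)
        multis = mut_count - singles
        net = 2 * rng.binomial(singles, 0.5) - singles
        m_tot = int(multis.sum())
        if m_tot:
            mags = rng.geometric(q_geom, size=m_tot)
            signs = rng.choice([-1, 1], size=m_tot)
            owner = np.repeat(np.arange(root), multis)
            net = net + np.bincount(owner, weights=mags * signs, minlength=root).astype(np.int64)
    for node in range(n_nodes - 2, -1, -1):
        states[node] = states[parent[node]] + net[node]
    return states[:n]


def _unbiased_het_from_states(states: np.ndarray) -> float:
    n = len(states)
    _, counts = np.unique(states, return_counts=True)
    sum_p2 = float(np.sum((counts / n) ** 2))
    return n / (n - 1.0) * (1.0 - sum_p2)


def _expected_k_iam(n: int, theta: float) -> float:
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


def _theta_for_k(n: int, k: int, model: MutationModel, rng: np.random.Generator) -> float:
    """Theta such that the expected sample allele number equals k.

    Closed form under IAM; bisection on pilot simulations for SMM/TPM (size
    homoplasy makes their expected allele count lower at equal theta).
    """
    if model.kind == IAM:
        lo, hi = 1e-6, 1e7
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if _expected_k_iam(n, mid) < k:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)
    pilot = 120
    lo, hi = 1e-4, 1e4

    def mean_k(theta: float) -> float:
        ks = [len(np.unique(_coalescent_leaf_states(n, theta, model, rng))) for _ in range(pilot)]
        return float(np.mean(ks))

    for _ in range(18):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(
    n_genes: int,
    k_obs: int,
    model: MutationModel,
    n_sim: int = 1000,
    seed: int | None = None,
    max_attempt_factor: int = 10_000,
) -> np.ndarray:
    """Equilibrium-heterozygosity distribution given sample size and allele count.

    Returns ``n_sim`` unbiased heterozygosity values from coalescent replicates
    that realized exactly ``k_obs`` alleles.
    """
    if not 1 <= k_obs <= n_genes:
        raise ValueError(f"k_obs must be in [1, n_genes], got {k_obs} vs {n_genes}")
    if k_obs == 1:
        return np.zeros(n_sim)
    rng = np.random.default_rng(seed)
    theta = _theta_for_k(n_genes, k_obs, model, rng)
    out = np.empty(n_sim)
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * n_sim
    while accepted < n_sim:
        if attempts >= max_attempts:
            rate = accepted / max(attempts, 1)
            raise RuntimeError(
                f"acceptance rate {rate:.2e} below 1e-4; review n_genes={n_genes}, k_obs={k_obs}"
            )
        states = _coalescent_leaf_states(n_genes, theta, model, rng)
        attempts += 1
        if len(np.unique(states)) == k_obs:
            out[accepted] = _unbiased_het_from_states(states)
            accepted += 1
    return out


# -------------------------------------------------------------- Wilcoxon test
def wilcoxon_one_tailed(dh: np.ndarray, exact_max_n: int = 25) -> float:
    """One-tailed Wilcoxon signed-rank p for median(dh) > 0.

    Exact null enumeration up to ``exact_max_n`` values, normal approximation
    above (the usual convention for locus-count-sized samples).
    """
    dh = np.asarray(dh, dtype=float)
    dh = dh[dh != 0.0]
    if dh.size == 0:
        return 1.0
    method = "exact" if dh.size <= exact_max_n else "approx"
    return float(stats.wilcoxon(dh, alternative="greater", method=method).pvalue)


def heterozygosity_excess_test(
    panel: GenotypePanel,
    population: str | None = None,
    by: str = "section",
    model: MutationModel = MutationModel(IAM),
    n_sim: int = 1000,
    seed: int | None = None,
) -> BottleneckReport:
    """Wilcoxon heterozygosity-excess bottleneck test for one mutation model.

    Per polymorphic locus, DH = (He_obs - mean Heq) / sd Heq; the one-tailed
    signed-rank test asks whether DH is centred above zero.
    """
    idx = _pop_indices(panel, population, by)
    rng = np.random.default_rng(seed)
    rows: list[LocusExcess] = []
    for loc in panel.loci:
        g = panel.genotypes(loc.name, idx)
        if g.shape[0] < 2:
            continue
        alleles, counts = np.unique(g, return_counts=True)
        if len(alleles) < 2:
            continue
        n_genes = 2 * g.shape[0]
        sum_p2 = float(np.sum((counts / n_genes) ** 2))
        he_obs = n_genes / (n_genes - 1.0) * (1.0 - sum_p2)
        heq = simulate_heq(n_genes, len(alleles), model, n_sim, seed=int(rng.integers(2**31)))
        mu, sd = float(heq.mean()), float(heq.std(ddof=1))
        dh = (he_obs - mu) / sd if sd > 0 else 0.0
        rows.append(LocusExcess(loc.name, he_obs, mu, sd, dh))
    if len(rows) < 4:
        raise ValueError("heterozygosity-excess test needs >= 4 polymorphic loci")
    dh = np.array([r.dh for r in rows])
    report = BottleneckReport(population=population or "all", n_sim=n_sim)
    report.per_locus[model.kind] = rows
    if np.all(dh == 0.0):
        p = 1.0
    else:
        p = wilcoxon_one_tailed(dh)
    setattr(report, {"IAM": "p_iam", "SMM": "p_smm", "TPM": "p_tpm"}[model.kind], p)
    return report


# ------------------------------------------------------------------- M-ratio
def m_ratio(panel: GenotypePanel, locus: str, population: str | None = None, by: str = "section") -> float:
    """Modified Garza-Williamson index M = k / (r + 1), r in repeat units.

    r = (max - min) / motif_length, rounded when the range is a clean multiple
    of the motif and floored otherwise (off-ladder alleles).  Monomorphic loci
    give M = 1 by convention (range 0, single allele).
    """
    idx = _pop_indices(panel, population, by)
    loc = panel.locus(locus)
    if loc.motif_length is None:
        raise ValueError(f"locus {locus} has no motif_length; M-ratio needs repeat units")
    g = panel.genotypes(locus, idx)
    if g.size == 0:
        raise ValueError(f"no genotypes at {locus}")
    alleles = np.unique(g)
    k = len(alleles)
    span = int(alleles.max() - alleles.min())
    if span % loc.motif_length == 0:
        r = span // loc.motif_length
    else:
        r = span // loc.motif_length  # off-ladder: floor division
    return k / (r + 1.0)


def m_ratio_mean(
    panel: GenotypePanel,
    population: str | None = None,
    by: str = "section",
    criterion: float = 0.68,
) -> tuple[float, bool]:
    """Arithmetic mean M over loci and whether it falls below the 0.68 criterion."""
    values = [m_ratio(panel, loc.name, population, by) for loc in panel.loci]
    mean = float(np.mean(values))
    return mean, mean < criterion
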
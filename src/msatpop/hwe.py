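"""Exact Hardy-Weinberg tests, genotypic LD tests and multiple-testing helpers.

The HWE test conditions on allele counts: small tables (<= 3 alleles and
<= 30 individuals) are handled by complete enumeration of genotype tables,
larger ones by the Guo-Thompson switch Markov chain.  "More extreme" means
lower conditional table probability (the Guo-Thompson convention), not a
statistic ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import GenotypePanel

__all__ = [
    "TestResult",
    "hwe_exact",
    "genotypic_ld_test",
    "sequential_bonferroni",
    "combine_p_fisher",
]


@dataclass
class TestResult:
    statistic: float | None
    p_value: float | None
    method: str
    n_permutations_or_steps: int = 0
    adjusted_significant: bool | None = None
    flag: str | None = None


# ------------------------------------------------------------------ HWE exact
def _genotype_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map genotypes to a lower-triangular count matrix f[i, j] (i >= j)."""
    alleles = np.unique(g)
    k = len(alleles)
    index = {int(a): i for i, a in enumerate(alleles)}
    f = np.zeros((k, k), dtype=np.int64)
    for a, b in g:
        i, j = index[int(a)], index[int(b)]
        lo, hi = min(i, j), max(i, j)
        f[hi, lo] += 1
    return f, alleles


def _log_table_prob(f: np.ndarray) -> float:
    """Log of the HWE-conditional table probability up to a table-free constant.

    P(f | allele counts) = n! * prod(a_i!) * 2^het / ((2n)! * prod(f_ij!));
    only the table-dependent part 2^het / prod(f_ij!) matters for comparisons.
    """
    het = int(f.sum() - np.trace(f))
    return het * math.log(2.0) - sum(math.lgamma(v + 1.0) for v in f[np.tril_indices_from(f)])


def _enumerate_tables(allele_counts: np.ndarray):
    """Yield every genotype table consistent with the given allele counts."""
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i + 1)]
    f = np.zeros((k, k), dtype=np.int64)
    remaining = allele_counts.astype(np.int64).copy()

    def contribution(i: int, j: int) -> int:
        return 2 if i == j else 1

    def rec(c: int):
        if c == len(cells):
            if remaining.sum() == 0:
                yield f.copy()
            return
        i, j = cells[c]
        if i == j:
            top = remaining[i] // 2
        else:
            top = min(remaining[i], remaining[j])
        for v in range(int(top) + 1):
            f[i, j] = v
            remaining[i] -= v * contribution(i, j) if i == j else v
            if i != j:
                remaining[j] -= v
            if remaining.min() >= 0:
                yield from rec(c + 1)
            remaining[i] += v * contribution(i, j) if i == j else v
            if i != j:
                remaining[j] += v
        f[i, j] = 0

    yield from rec(0)


def _hwe_enumeration(f_obs: np.ndarray) -> float:
    # copies of allele i = 2*f[i,i] + off-diagonal cells touching i
    k = f_obs.shape[0]
    allele_counts = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                allele_counts[i] += 2 * f_obs[i, j]
            else:
                allele_counts[i] += f_obs[i, j]
                allele_counts[j] += f_obs[i, j]
    lp_obs = _log_table_prob(f_obs)
    num = 0.0
    den = 0.0
    for table in _enumerate_tables(allele_counts):
        lp = _log_table_prob(table)
        w = math.exp(lp - lp_obs)
        den += w
        if lp <= lp_obs + 1e-12:
            num += w
    return num / den


def _hwe_mcmc(g: np.ndarray, steps: int, dememorization: int, rng: np.random.Generator) -> float:
    """Switch Markov chain on the 2n gene copies (Guo-Thompson style).

    The chain transposes two gene copies between individuals each step.  The
    uniform distribution over copy pairings induces exactly the HWE
    conditional distribution on genotype tables, so every switch is accepted
    and the p-value is the visit fraction of tables no more probable than the
    observed one.
    """
    n = g.shape[0]
    _, alleles = _genotype_counts(g)
    index = {int(a): i for i, a in enumerate(alleles)}
    flat = np.array([index[int(a)] for a in g.ravel()], dtype=np.int64)  # slot 2i, 2i+1

    counts: dict[tuple[int, int], int] = {}
    het = 0
    for i in range(n):
        a, b = int(flat[2 * i]), int(flat[2 * i + 1])
        key = (max(a, b), min(a, b))
        counts[key] = counts.get(key, 0) + 1
        if a != b:
            het += 1
    lp = het * math.log(2.0) - sum(math.lgamma(v + 1.0) for v in counts.values())
    lp_obs = lp

    total = steps + dememorization
    s1 = rng.integers(0, 2 * n, size=total)
    s2 = rng.integers(0, 2 * n, size=total)
    log2 = math.log(2.0)

    below = 0
    kept = 0
    for t in range(total):
        a_slot, b_slot = int(s1[t]), int(s2[t])
        u, v = a_slot // 2, b_slot // 2
        if u != v and flat[a_slot] != flat[b_slot]:
            gu = (int(flat[2 * u]), int(flat[2 * u + 1]))
            gv = (int(flat[2 * v]), int(flat[2 * v + 1]))
            flat[a_slot], flat[b_slot] = flat[b_slot], flat[a_slot]
            nu = (int(flat[2 * u]), int(flat[2 * u + 1]))
            nv = (int(flat[2 * v]), int(flat[2 * v + 1]))
            for (a, b), sign in ((gu, -1), (gv, -1), (nu, +1), (nv, +1)):
                key = (max(a, b), min(a, b))
                c = counts.get(key, 0)
                if sign < 0:
                    lp += math.log(c)  # f! -> (f-1)!
                    counts[key] = c - 1
                    if a != b:
                        lp -= log2
                else:
                    lp -= math.log(c + 1.0)
                    counts[key] = c + 1
                    if a != b:
                        lp += log2
        if t >= dememorization:
            kept += 1
            if lp <= lp_obs + 1e-9:
                below += 1
    return below / max(kept, 1)


def hwe_exact(
    panel: GenotypePanel,
    locus: str,
    population: str | None = None,
    by: str = "section",
    steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Exact Hardy-Weinberg test conditioning on allele counts.

    Complete enumeration for <= 3 alleles and <= 30 individuals; otherwise the
    Guo-Thompson Markov chain with the requested number of steps.
    """
    from .diversity import _pop_indices

    idx = _pop_indices(panel, population, by)
    g = panel.genotypes(locus, idx)
    if g.shape[0] == 0:
        raise ValueError(f"no genotypes at {locus}")
    alleles = np.unique(g)
    if len(alleles) == 1:
        return TestResult(None, 1.0, "monomorphic", 0, flag="monomorphic")
    f_obs, _ = _genotype_counts(g)
    if len(alleles) <= 3 and g.shape[0] <= 30:
        p = _hwe_enumeration(f_obs)
        return TestResult(None, float(min(p, 1.0)), "enumeration", 0)
    rng = np.random.default_rng(seed)
    p = _hwe_mcmc(g, steps, dememorization, rng)
    return TestResult(None, float(p), "mcmc", steps)


# ----------------------------------------------------------- genotypic LD test
def _g_statistic(table: np.ndarray) -> float:
    table = table.astype(float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def genotypic_ld_test(
    panel: GenotypePanel,
    locus_pair: tuple[str, str],
    population: str | None = None,
    by: str = "section",
    permutations: int = 1000,
    seed: int | None = None,
) -> TestResult:
    """Log-likelihood G test of association between two-locus genotype tables.

    The null distribution comes from permuting one locus's genotypes among
    individuals, which preserves both single-locus genotype distributions.
    """
    from .diversity import _pop_indices

    la, lb = locus_pair
    idx = _pop_indices(panel, population, by)
    ja, jb = panel.locus_index(la), panel.locus_index(lb)
    calls = panel.calls if idx is None else panel.calls[idx]
    ok = (calls[:, ja, 0] != -1) & (calls[:, jb, 0] != -1)
    if ok.sum() < 10:
        return TestResult(None, None, "g-permutation", 0, flag="fewer than 10 shared individuals")
    ga = calls[ok, ja, :]
    gb = calls[ok, jb, :]

    def codes(g: np.ndarray) -> np.ndarray:
        pairs = [tuple(row) for row in g]
        uniq = {p: i for i, p in enumerate(sorted(set(pairs)))}
        return np.array([uniq[p] for p in pairs]), len(uniq)

    ca, na = codes(ga)
    cb, nb = codes(gb)
    if na == 1 or nb == 1:
        return TestResult(0.0, 1.0, "g-permutation", 0, flag="constant locus")
    table = np.zeros((na, nb), dtype=np.int64)
    np.add.at(table, (ca, cb), 1)
    g_obs = _g_statistic(table)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(cb)
        t = np.zeros((na, nb), dtype=np.int64)
        np.add.at(t, (ca, perm), 1)
        if _g_statistic(t) >= g_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (permutations + 1.0)
    return TestResult(g_obs, float(p), "g-permutation", permutations)


# ------------------------------------------------------- multiple testing etc.
def sequential_bonferroni(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Holm step-down correction; flags returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break
    return flags.tolist()


def combine_p_fisher(p_values: list[float]) -> TestResult:
    """Fisher's combination: X^2 = -2 sum ln p, df = 2m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    flag = None
    if (p == 0).any():
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        flag = "zero p-values clamped to machine minimum"
    x2 = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(x2, df=2 * p.size))
    return TestResult(x2, combined, "fisher", 0, flag=flag)
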
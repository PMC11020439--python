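"""Genetic differentiation: Weir-Cockerham FST, standardized F'ST, Jost's DEST,
allele-level AMOVA and exact G-tests of allele-frequency heterogeneity.

F'ST standardizes theta by its maximum, obtained by recoding alleles so no
allele is shared between populations while keeping each population's genotype
structure intact.  AMOVA partitions allele-identity variance among and within
populations at the gene-copy level (each individual contributes two copies).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .hwe import TestResult, _g_statistic, combine_p_fisher
from .panel import GenotypePanel, MISSING

__all__ = [
    "PairwiseMatrix",
    "AmovaTable",
    "fst_weir_cockerham",
    "fst_standardized",
    "jost_dest",
    "amova",
    "g_test_differentiation",
]


@dataclass
class PairwiseMatrix:
    labels: list[str]
    values: np.ndarray
    p_values: np.ndarray | None = None
    statistic: str = ""


@dataclass
class AmovaTable:
    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    var_among: float           # may be negative; reported as computed
    var_within: float
    phi_st: float              # derived from raw components
    phi_st_floored: float      # summary view, floored at 0
    p_value: float | None = None
    n_permutations: int = 0


# -------------------------------------------------- Weir-Cockerham components
def _pop_genotypes(panel: GenotypePanel, by: str, populations: list[str] | None) -> dict[str, np.ndarray]:
    groups = panel.group_indices(by)
    if populations is not None:
        missing = set(populations) - set(groups)
        if missing:
            raise KeyError(f"unknown populations {sorted(missing)} under grouping {by!r}")
        groups = {k: groups[k] for k in populations}
    if len(groups) < 2:
        raise ValueError("differentiation needs >= 2 populations")
    return groups


def _wc_abc_for_calls(per_pop_geno: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed WC84 variance components (a, b, c) over alleles for one locus."""
    per_pop_geno = [g for g in per_pop_geno if g.shape[0] >= 2]
    r = len(per_pop_geno)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([g.shape[0] for g in per_pop_geno], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - float(np.sum(ns**2)) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in per_pop_geno]))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([float((g == al).sum()) / (2 * g.shape[0]) for g in per_pop_geno])
        h_i = np.array([float(np.mean(((g == al).sum(axis=1) == 1))) for g in per_pop_geno])
        pbar = float(np.sum(ns * p_i) / (r * nbar))
        s2 = float(np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(ns * h_i) / (r * nbar))
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def fst_weir_cockerham(
    panel: GenotypePanel,
    populations: list[str] | None = None,
    by: str = "section",
) -> tuple[float, dict[str, tuple[float, float, float]]]:
    """Multilocus Weir-Cockerham theta with per-locus (a, b, c) components."""
    groups = _pop_genotypes(panel, by, populations)
    per_locus: dict[str, tuple[float, float, float]] = {}
    A = B = C = 0.0
    for loc in panel.loci:
        genos = [panel.genotypes(loc.name, idx) for idx in groups.values()]
        a, b, c = _wc_abc_for_calls(genos)
        per_locus[loc.name] = (a, b, c)
        A += a
        B += b
        C += c
    total = A + B + C
    theta = A / total if total > 0 else 0.0
    return float(theta), per_locus


def _recode_disjoint(panel: GenotypePanel, groups: dict[str, np.ndarray]) -> GenotypePanel:
    """Shift allele sizes per population so no allele is shared across populations."""
    calls = panel.calls.copy()
    for k, (label, idx) in enumerate(groups.items()):
        block = calls[idx]
        shift = (k + 1) * 1_000_000
        block[block != MISSING] += shift
        calls[idx] = block
    return GenotypePanel(
        [type(loc)(loc.name, loc.motif_length) for loc in panel.loci], panel.individuals, calls
    )


def fst_standardized(
    panel: GenotypePanel,
    populations: list[str] | None = None,
    by: str = "section",
    n_permutations: int = 0,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """F'ST = FST / FST_max via the allele-recoding method, optional permutation p."""
    groups = _pop_genotypes(panel, by, populations)
    sub = panel.subset(np.concatenate(list(groups.values())))
    theta, _ = fst_weir_cockerham(panel, list(groups), by)
    groups_sub = sub.group_indices(by)
    groups_sub = {k: groups_sub[k] for k in groups}
    recoded = _recode_disjoint(sub, groups_sub)
    theta_max, _ = fst_weir_cockerham(recoded, list(groups), by)
    fprime = theta / theta_max if theta_max > 0 else 0.0
    p_val = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        labels = np.concatenate([[lab] * len(ix) for lab, ix in groups_sub.items()])
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            inds = [type(ind)(ind.id, section=str(s)) for ind, s in zip(sub.individuals, perm)]
            shuffled = GenotypePanel(sub.loci, inds, sub.calls)
            t, _ = fst_weir_cockerham(shuffled, by="section")
            g2 = {k: v for k, v in shuffled.group_indices("section").items()}
            tm, _ = fst_weir_cockerham(_recode_disjoint(shuffled, g2), by="section")
            f = t / tm if tm > 0 else 0.0
            if f >= fprime - 1e-12:
                exceed += 1
        p_val = (1.0 + exceed) / (n_permutations + 1.0)
    return float(fprime), p_val


# ---------------------------------------------------------------------- Jost D
def _jost_d_locus(per_pop_geno: list[np.ndarray]) -> float | None:
    per_pop_geno = [g for g in per_pop_geno if g.shape[0] >= 1]
    r = len(per_pop_geno)
    if r < 2:
        return None
    ns = np.array([g.shape[0] for g in per_pop_geno], dtype=float)
    n_harm = r / float(np.sum(1.0 / ns))
    alleles = np.unique(np.concatenate([g.ravel() for g in per_pop_geno]))
    freqs = np.array([
        [float((g == al).sum()) / (2 * g.shape[0]) for al in alleles] for g in per_pop_geno
    ])
    hs_raw = 1.0 - float(np.mean(np.sum(freqs**2, axis=1)))
    hs = (2.0 * n_harm / (2.0 * n_harm - 1.0)) * hs_raw
    pbar = freqs.mean(axis=0)
    ht_raw = 1.0 - float(np.sum(pbar**2))
    ht = ht_raw + hs / (2.0 * n_harm * r)
    if hs >= 1.0:
        return None
    return (r / (r - 1.0)) * (ht - hs) / (1.0 - hs)


def jost_dest(
    panel: GenotypePanel,
    populations: list[str] | None = None,
    by: str = "section",
) -> tuple[float, dict[str, float | None]]:
    """Jost's DEST (sample-size corrected) per locus and the multilocus value.

    The multilocus aggregate uses the 1/D - 1 transformed (harmonic-style)
    averaging of per-locus values, flooring non-positive per-locus D at 1e-9.
    """
    groups = _pop_genotypes(panel, by, populations)
    per_locus: dict[str, float | None] = {}
    transformed = []
    for loc in panel.loci:
        genos = [panel.genotypes(loc.name, idx) for idx in groups.values()]
        d = _jost_d_locus(genos)
        per_locus[loc.name] = d
        if d is not None:
            transformed.append(1.0 / max(d, 1e-9) - 1.0)
    if not transformed:
        raise ValueError("Jost D undefined at every locus")
    d_multi = 1.0 / (1.0 + float(np.mean(transformed)))
    return float(d_multi), per_locus


# ----------------------------------------------------------------------- AMOVA
def _amova_ss(panel: GenotypePanel, groups: dict[str, np.ndarray]) -> tuple[float, float, float, np.ndarray]:
    """Allele-identity sums of squares (among, within, total) over all loci."""
    ss_within = 0.0
    ss_total = 0.0
    copies_per_pop = np.zeros(len(groups))
    for j, loc in enumerate(panel.loci):
        all_copies = []
        for k, idx in enumerate(groups.values()):
            g = panel.calls[idx, j, :]
            g = g[g[:, 0] != MISSING]
            copies = g.ravel()
            all_copies.append(copies)
            m = len(copies)
            if m > 1:
                _, counts = np.unique(copies, return_counts=True)
                ss_within += (m - float(np.sum(counts**2)) / m) / 2.0
        pooled = np.concatenate(all_copies)
        m = len(pooled)
        if m > 1:
            _, counts = np.unique(pooled, return_counts=True)
            ss_total += (m - float(np.sum(counts**2)) / m) / 2.0
    for k, idx in enumerate(groups.values()):
        g0 = panel.calls[idx, :, 0]
        copies_per_pop[k] = 2 * len(idx)  # nominal copy count (df bookkeeping)
    ss_among = ss_total - ss_within
    return ss_among, ss_within, ss_total, copies_per_pop


def amova(
    panel: GenotypePanel,
    grouping: str = "section",
    populations: list[str] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaTable:
    """Two-level allele-based AMOVA with permutation significance.

    Individuals (both gene copies together) are permuted among groups.  df are
    gene-copy level: among = g - 1, within = 2N - g, total = 2N - 1.
    """
    groups = _pop_genotypes(panel, grouping, populations)
    g = len(groups)
    n_total = int(sum(len(ix) for ix in groups.values()))
    ss_among, ss_within, ss_total, copies = _amova_ss(panel, groups)
    df_among = g - 1
    df_within = 2 * n_total - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (copies.sum() - float(np.sum(copies**2)) / copies.sum()) / (g - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    total_var = var_among + var_within
    phi = var_among / total_var if total_var > 0 else 0.0
    table = AmovaTable(
        df_among=df_among,
        df_within=df_within,
        df_total=2 * n_total - 1,
        ss_among=ss_among,
        ss_within=ss_within,
        var_among=var_among,
        var_within=var_within,
        phi_st=float(phi),
        phi_st_floored=float(max(phi, 0.0)),
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        all_idx = np.concatenate(list(groups.values()))
        sizes = [len(ix) for ix in groups.values()]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(all_idx)
            start = 0
            pg: dict[str, np.ndarray] = {}
            for lab, size in zip(groups, sizes):
                pg[lab] = perm[start : start + size]
                start += size
            sa, sw, _, cp = _amova_ss(panel, pg)
            msa = sa / df_among
            msw = sw / df_within
            va = (msa - msw) / n0
            tot = va + msw
            ph = va / tot if tot > 0 else 0.0
            if ph >= phi - 1e-12:
                exceed += 1
        table.p_value = (1.0 + exceed) / (n_permutations + 1.0)
        table.n_permutations = n_permutations
    return table


# --------------------------------------------------------------------- G-test
def _contingency_mcmc_p(
    table: np.ndarray,
    dememorization: int,
    batches: int,
    iters_per_batch: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Exact test of homogeneity by a Markov chain over fixed-margin tables.

    Swap moves with Metropolis acceptance under the hypergeometric table
    probability; the p-value is the visit fraction with G >= G_observed,
    with a batch-based standard error (Genepop's scheme).
    """
    t = table.astype(np.int64).copy()
    rows, cols = t.shape
    row_tot = t.sum(axis=1)
    col_tot = t.sum(axis=0)
    total = t.sum()
    expected = np.outer(row_tot, col_tot) / total

    def cell_g(v: np.ndarray, i: int, j: int) -> float:
        x = v[i, j]
        return 0.0 if x == 0 else 2.0 * x * np.log(x / expected[i, j])

    g_obs = _g_statistic(t)
    g_cur = g_obs

    def step() -> None:
        nonlocal g_cur
        i1, i2 = rng.integers(rows), rng.integers(rows)
        j1, j2 = rng.integers(cols), rng.integers(cols)
        if i1 == i2 or j1 == j2:
            return
        if t[i1, j2] == 0 or t[i2, j1] == 0:
            # try the reverse direction move
            if t[i1, j1] == 0 or t[i2, j2] == 0:
                return
            i1, i2 = i2, i1
        # move: +1 at (i1,j1),(i2,j2); -1 at (i1,j2),(i2,j1)
        ratio = (t[i1, j2] * t[i2, j1]) / ((t[i1, j1] + 1.0) * (t[i2, j2] + 1.0))
        if rng.random() < ratio:
            old = sum(cell_g(t, i, j) for i in (i1, i2) for j in (j1, j2))
            t[i1, j1] += 1
            t[i2, j2] += 1
            t[i1, j2] -= 1
            t[i2, j1] -= 1
            new = sum(cell_g(t, i, j) for i in (i1, i2) for j in (j1, j2))
            g_cur += new - old

    for _ in range(dememorization):
        step()
    batch_means = []
    for _ in range(batches):
        hits = 0
        for _ in range(iters_per_batch):
            step()
            if g_cur >= g_obs - 1e-9:
                hits += 1
        batch_means.append(hits / iters_per_batch)
    p = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / np.sqrt(batches)) if batches > 1 else 0.0
    return p, se


def g_test_differentiation(
    panel: GenotypePanel,
    populations: list[str] | None = None,
    by: str = "section",
    dememorization: int = 10_000,
    batches: int = 100,
    iters_per_batch: int = 5_000,
    seed: int | None = None,
) -> tuple[dict[str, TestResult], TestResult]:
    """Per-locus exact G-test of allele-frequency heterogeneity + Fisher global."""
    groups = _pop_genotypes(panel, by, populations)
    rng = np.random.default_rng(seed)
    per_locus: dict[str, TestResult] = {}
    ps = []
    for loc in panel.loci:
        genos = [panel.genotypes(loc.name, idx) for idx in groups.values()]
        alleles = np.unique(np.concatenate([g.ravel() for g in genos if g.size]))
        if len(alleles) < 2:
            per_locus[loc.name] = TestResult(None, None, "g-exact-mcmc", 0, flag="monomorphic, skipped")
            continue
        table = np.array([
            [int((g == al).sum()) for al in alleles] for g in genos
        ])
        g_obs = _g_statistic(table)
        if g_obs <= 1e-12:
            per_locus[loc.name] = TestResult(0.0, 1.0, "g-exact-mcmc", 0)
            ps.append(1.0)
            continue
        p, se = _contingency_mcmc_p(
            table, dememorization, batches, iters_per_batch, rng
        )
        res = TestResult(g_obs, p, "g-exact-mcmc", batches * iters_per_batch)
        res.flag = f"se={se:.2g}"
        per_locus[loc.name] = res
        ps.append(max(p, 1.0 / (batches * iters_per_batch)))  # MCMC zero guard
    if not ps:
        raise ValueError("no polymorphic loci for the G-test")
    global_res = combine_p_fisher(ps)
    return per_locus, global_res


# ----------------------------------------------------------- pairwise matrices
def pairwise_matrix(
    panel: GenotypePanel,
    statistic: str = "fst_standardized",
    by: str = "section",
    n_permutations: int = 0,
    seed: int | None = None,
) -> PairwiseMatrix:
    """Symmetric pairwise matrix of F'ST or Jost's DEST with optional p-values."""
    groups = panel.group_indices(by)
    labels = list(groups)
    k = len(labels)
    values = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_permutations else None
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(k), 2):
        pair = [labels[i], labels[j]]
        if statistic == "fst_standardized":
            v, p = fst_standardized(
                panel, pair, by, n_permutations, seed=int(rng.integers(2**31))
            )
        elif statistic == "jost_dest":
            v, _ = jost_dest(panel, pair, by)
            p = None
        elif statistic == "fst":
            v, _ = fst_weir_cockerham(panel, pair, by)
            p = None
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        values[i, j] = values[j, i] = v
        if pvals is not None and p is not None:
            pvals[i, j] = pvals[j, i] = p
    return PairwiseMatrix(labels, values, pvals, statistic)
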
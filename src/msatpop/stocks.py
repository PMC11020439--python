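"""Genetic stock inference: admixture-model Gibbs sampling over K, replicate
alignment, Evanno delta-K and Puechmaille K-selectors, a compact DAPC, and
seasonal stock-composition summaries.

The sampler implements the admixture model with independent allele
frequencies: each gene copy carries a latent cluster assignment; cluster
allele frequencies get a Dirichlet(1) prior and individual membership vectors
a symmetric Dirichlet(alpha) prior with alpha fixed (default 1.0).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .panel import GenotypePanel, MISSING

__all__ = [
    "AdmixtureRun",
    "QMatrixEnsemble",
    "KSelection",
    "SeasonComposition",
    "admixture_mcmc",
    "run_k_grid",
    "align_replicates",
    "select_k",
    "dapc_lite",
    "season_composition",
]


@dataclass
class AdmixtureRun:
    K: int
    replicate: int
    log_likelihood: float
    Q: np.ndarray            # individuals x K, rows sum to 1
    seed: int
    converged: bool = True


@dataclass
class QMatrixEnsemble:
    runs: list[AdmixtureRun] = field(default_factory=list)

    def at_k(self, K: int) -> list[AdmixtureRun]:
        return [r for r in self.runs if r.K == K]

    @property
    def ks(self) -> list[int]:
        return sorted({r.K for r in self.runs})


@dataclass
class KSelection:
    delta_k: dict[int, float]
    med_mean_k: int
    max_mean_k: int
    med_med_k: int
    max_med_k: int
    chosen_k: int
    membership_threshold: float


def _encode(panel: GenotypePanel) -> tuple[list[np.ndarray], list[int]]:
    """Per locus: allele-index codes (n, 2) with -1 for missing, and allele counts."""
    codes = []
    sizes = []
    for j, loc in enumerate(panel.loci):
        g = panel.calls[:, j, :]
        alleles = np.unique(g[g != MISSING])
        lookup = {int(a): i for i, a in enumerate(alleles)}
        c = np.full_like(g, -1, dtype=np.int64)
        for a, i in lookup.items():
            c[g == a] = i
        codes.append(c)
        sizes.append(len(alleles))
    return codes, sizes


def _update_alpha(alpha: float, q: np.ndarray, rng: np.random.Generator) -> float:
    """Metropolis update of the admixture concentration, Uniform(0, 10) prior."""
    from scipy.special import gammaln

    n, K = q.shape
    log_q_sum = float(np.log(q).sum())

    def logpost(a: float) -> float:
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * log_q_sum

    prop = alpha + rng.normal(0.0, 0.05)
    if not 0.0 < prop < 10.0:
        return alpha
    if np.log(rng.random()) < logpost(prop) - logpost(alpha):
        return prop
    return alpha


def admixture_mcmc(
    panel: GenotypePanel,
    K: int,
    steps: int = 50_000,
    burn_in: int = 10_000,
    seed: int | None = None,
    alpha: float = 1.0,
    freq_prior: float = 1.0,
    sample_alpha: bool = False,
    replicate: int = 0,
) -> AdmixtureRun:
    """One Gibbs-sampler run of the admixture model at a fixed K.

    Returns the posterior-mean membership matrix Q and the posterior-mean data
    log-likelihood L(K).  With ``sample_alpha`` the admixture concentration is
    given a Uniform(0, 10) prior and updated by a Metropolis step each sweep
    (small inferred alpha concentrates memberships, as in strongly structured
    data); otherwise alpha stays fixed.  A split-half difference in the
    likelihood trace larger than 3 trace standard deviations flags
    non-convergence (the run is still returned).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if steps <= burn_in:
        raise ValueError("steps must exceed burn_in")
    rng = np.random.default_rng(seed)
    codes, k_alleles = _encode(panel)
    n = panel.n_individuals
    L = panel.n_loci

    z = [rng.integers(0, K, size=c.shape) for c in codes]  # cluster of each copy
    q = np.full((n, K), 1.0 / K)
    q_sum = np.zeros((n, K))
    ll_trace = []
    kept = 0

    for sweep in range(steps):
        # allele frequencies per cluster | z
        p = []
        for j in range(L):
            counts = np.zeros((K, k_alleles[j]))
            valid = codes[j] >= 0
            np.add.at(counts, (z[j][valid], codes[j][valid]), 1.0)
            gam = rng.gamma(freq_prior + counts)
            p.append(gam / gam.sum(axis=1, keepdims=True))
        # memberships | z
        assign = np.zeros((n, K))
        for j in range(L):
            valid = codes[j] >= 0
            ind_idx = np.repeat(np.arange(n)[:, None], 2, axis=1)
            np.add.at(assign, (ind_idx[valid], z[j][valid]), 1.0)
        gam = rng.gamma(alpha + assign)
        q = gam / gam.sum(axis=1, keepdims=True)
        q = np.clip(q, 1e-300, None)
        q /= q.sum(axis=1, keepdims=True)
        if sample_alpha and K > 1:
            alpha = _update_alpha(alpha, q, rng)
        # copy assignments | p, q  and data log-likelihood
        ll = 0.0
        for j in range(L):
            for copy in (0, 1):
                a = codes[j][:, copy]
                valid = a >= 0
                if not valid.any():
                    continue
                w = q[valid] * p[j][:, a[valid]].T  # (m, K)
                tot = w.sum(axis=1)
                ll += float(np.log(tot).sum())
                u = rng.random(valid.sum()) * tot
                z[j][valid, copy] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
        if sweep >= burn_in:
            q_sum += q
            ll_trace.append(ll)
            kept += 1

    ll_trace_arr = np.asarray(ll_trace)
    half = kept // 2
    converged = True
    if half > 1:
        sd = ll_trace_arr.std(ddof=1)
        if sd > 0 and abs(ll_trace_arr[:half].mean() - ll_trace_arr[half:].mean()) > 3 * sd:
            converged = False
    Q = q_sum / kept
    return AdmixtureRun(
        K=K,
        replicate=replicate,
        log_likelihood=float(ll_trace_arr.mean()),
        Q=Q,
        seed=seed if seed is not None else -1,
        converged=converged,
    )


def run_k_grid(
    panel: GenotypePanel,
    k_values: list[int],
    replicates: int = 20,
    steps: int = 50_000,
    burn_in: int = 10_000,
    seed: int | None = None,
    alpha: float = 1.0,
    sample_alpha: bool = True,
) -> QMatrixEnsemble:
    """Replicated admixture runs over a grid of K values.

    The ensemble layer infers the admixture concentration by default (the
    standard protocol): with alpha fixed at 1, spurious clusters at K above
    the true value retain membership mass and the group-membership
    K-estimators degenerate.
    """
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(len(k_values) * replicates) % (2**31))
    ens = QMatrixEnsemble()
    for K in k_values:
        for rep in range(replicates):
            s = int(next(child))
            ens.runs.append(
                admixture_mcmc(
                    panel, K, steps, burn_in, seed=s, alpha=alpha,
                    sample_alpha=sample_alpha, replicate=rep,
                )
            )
    return ens


def align_replicates(ensemble: QMatrixEnsemble) -> QMatrixEnsemble:
    """Resolve label switching: permute each replicate's clusters to match the
    first replicate at the same K (Hungarian assignment on Q-column products)."""
    out = QMatrixEnsemble()
    for K in ensemble.ks:
        runs = ensemble.at_k(K)
        ref = runs[0]
        out.runs.append(ref)
        for run in runs[1:]:
            if K == 1:
                out.runs.append(run)
                continue
            score = ref.Q.T @ run.Q  # (K, K) similarity
            row, col = linear_sum_assignment(-score)
            perm = np.empty(K, dtype=int)
            perm[row] = col
            aligned = AdmixtureRun(
                K=run.K,
                replicate=run.replicate,
                log_likelihood=run.log_likelihood,
                Q=run.Q[:, perm],
                seed=run.seed,
                converged=run.converged,
            )
            out.runs.append(aligned)
    return out


def _puechmaille_counts(
    runs: list[AdmixtureRun], group_rows: dict[str, np.ndarray], threshold: float
) -> tuple[list[int], list[int]]:
    """Per replicate: number of clusters whose mean (median) membership within
    at least one predefined group exceeds the threshold; floored at 1."""
    mean_counts, med_counts = [], []
    for run in runs:
        mean_hit = med_hit = 0
        for k in range(run.K):
            col = run.Q[:, k]
            means = [float(col[rows].mean()) for rows in group_rows.values()]
            meds = [float(np.median(col[rows])) for rows in group_rows.values()]
            if max(means) > threshold:
                mean_hit += 1
            if max(meds) > threshold:
                med_hit += 1
        mean_counts.append(max(mean_hit, 1))
        med_counts.append(max(med_hit, 1))
    return mean_counts, med_counts


def select_k(
    ensemble: QMatrixEnsemble,
    panel: GenotypePanel | None = None,
    threshold: float = 0.5,
    group_by: str = "section",
) -> KSelection:
    """Evanno delta-K plus the four Puechmaille estimators; modal choice of K.

    delta-K needs >= 3 consecutive K values with replicated runs; the
    Puechmaille estimators need predefined groups (river sections by default):
    per replicate the clusters dominating at least one group are counted,
    counts are summarized per K, and the estimators take the median/maximum
    of that profile across the K grid.
    """
    ks = ensemble.ks
    mean_l = {K: float(np.mean([r.log_likelihood for r in ensemble.at_k(K)])) for K in ks}
    sd_l = {K: float(np.std([r.log_likelihood for r in ensemble.at_k(K)], ddof=1))
            if len(ensemble.at_k(K)) > 1 else 0.0 for K in ks}
    delta_k: dict[int, float] = {}
    for i in range(1, len(ks) - 1):
        k_prev, k, k_next = ks[i - 1], ks[i], ks[i + 1]
        if k - k_prev == 1 and k_next - k == 1:
            if sd_l[k] > 0:
                delta_k[k] = abs(mean_l[k_next] - 2 * mean_l[k] + mean_l[k_prev]) / sd_l[k]
            else:
                delta_k[k] = float("nan")

    votes: list[int] = []
    finite = {k: v for k, v in delta_k.items() if np.isfinite(v)}
    if finite:
        votes.append(max(finite, key=finite.get))

    if panel is not None:
        group_rows = panel.group_indices(group_by)
        if group_rows:
            aligned = align_replicates(ensemble)
            mean_per_k, med_per_k = [], []
            for K in ks:
                mean_counts, med_counts = _puechmaille_counts(
                    aligned.at_k(K), group_rows, threshold
                )
                mean_per_k.append(float(np.mean(mean_counts)))
                med_per_k.append(float(np.median(med_counts)))
            # summarize the per-K cluster counts across the K grid: the count
            # plateaus at the true K, so the maximum (and the median of the
            # profile) estimate it robustly even when extra clusters split
            mmk = int(np.round(np.median(mean_per_k)))
            xmk = int(np.round(np.max(mean_per_k)))
            mdk = int(np.round(np.median(med_per_k)))
            xdk = int(np.round(np.max(med_per_k)))
            votes.extend([mmk, xmk, mdk, xdk])
        else:
            mmk = xmk = mdk = xdk = 1
    else:
        mmk = xmk = mdk = xdk = 1

    if votes:
        counts = Counter(votes)
        top = max(counts.values())
        chosen = min(k for k, c in counts.items() if c == top)
    else:
        chosen = ks[0]
    return KSelection(delta_k, mmk, xmk, mdk, xdk, chosen, threshold)


# ------------------------------------------------------------------ DAPC-lite
def one_hot_allele_counts(panel: GenotypePanel) -> np.ndarray:
    """Individuals x allele dosage matrix; missing cells imputed at column means."""
    blocks = []
    for j, loc in enumerate(panel.loci):
        g = panel.calls[:, j, :]
        alleles = np.asarray(loc.allele_register)
        dose = (g[:, :, None] == alleles[None, None, :]).sum(axis=1).astype(float)
        miss = g[:, 0] == MISSING
        if miss.any():
            col_mean = dose[~miss].mean(axis=0) if (~miss).any() else np.zeros(len(alleles))
            dose[miss] = col_mean
        blocks.append(dose)
    return np.concatenate(blocks, axis=1)


def dapc_lite(
    panel: GenotypePanel,
    group_labels: list[str],
    n_pcs: int | str = "cv",
    cv_folds: int = 5,
    seed: int | None = None,
):
    """Discriminant analysis of principal components on allele dosages.

    PCA reduces the one-hot allele-count matrix; LDA separates the groups in
    the retained space.  ``n_pcs="cv"`` picks the component count by grouped
    cross-validation.  Returns coordinates, centroids and CV accuracy.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import make_pipeline

    y = np.asarray(group_labels)
    if len(y) != panel.n_individuals:
        raise ValueError("one group label per individual required")
    n_groups = len(set(y.tolist()))
    if n_groups < 2:
        raise ValueError("DAPC needs >= 2 groups")
    X = one_hot_allele_counts(panel)
    X = X - X.mean(axis=0)
    max_pcs = min(X.shape[0] - n_groups - 1, X.shape[1])

    def build(npc: int):
        return make_pipeline(PCA(n_components=npc, random_state=0),
                             LinearDiscriminantAnalysis())

    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    if n_pcs == "cv":
        grid = sorted({max(2, max_pcs // 8), max_pcs // 4, max_pcs // 2, int(0.8 * max_pcs)})
        grid = [g for g in grid if 2 <= g <= max_pcs]
        scores = {g: float(np.mean(cross_val_score(build(g), X, y, cv=cv))) for g in grid}
        n_pcs = max(scores, key=scores.get)
    elif not 1 <= int(n_pcs) <= max_pcs:
        raise ValueError(
            f"n_pcs must be < N - n_groups (= {max_pcs + 1}) to avoid overfitting"
        )
    n_pcs = int(n_pcs)
    accuracy = float(np.mean(cross_val_score(build(n_pcs), X, y, cv=cv)))
    pipe = build(n_pcs).fit(X, y)
    coords = pipe.transform(X)
    lda: "LinearDiscriminantAnalysis" = pipe.named_steps["lineardiscriminantanalysis"]
    pca = pipe.named_steps["pca"]
    centroids = {
        lab: coords[y == lab].mean(axis=0) for lab in sorted(set(y.tolist()))
    }
    return {
        "coordinates": coords,
        "centroids": centroids,
        "accuracy": accuracy,
        "n_pcs": n_pcs,
        "classes": list(lda.classes_),
    }


# ------------------------------------------------------- season composition
@dataclass
class SeasonComposition:
    cells: dict[tuple[str, int], dict[str, float]]   # (season, year) -> stock -> percent
    counts: dict[tuple[str, int], dict[str, int]]
    q_threshold: float


def season_composition(
    panel: GenotypePanel,
    q_matrix: np.ndarray | None = None,
    stock_names: list[str] | None = None,
    q_threshold: float = 0.5,
) -> SeasonComposition:
    """Stock percentages per (season, year) cell.

    Individuals are assigned to their argmax cluster when that membership is
    at least ``q_threshold`` and strictly unique; ties or sub-threshold rows
    count as "admixed" and are excluded from the percentages.
    """
    seasons = [ind.season for ind in panel.individuals]
    years = [ind.year for ind in panel.individuals]
    if all(s == "unknown" for s in seasons):
        raise ValueError("panel has no seasonal metadata")
    if q_matrix is not None:
        K = q_matrix.shape[1]
        names = stock_names or [f"Stock{k + 1}" for k in range(K)]
        assigned = []
        for row in q_matrix:
            top = float(row.max())
            if top < q_threshold or (row == top).sum() > 1:
                assigned.append("admixed")
            else:
                assigned.append(names[int(row.argmax())])
    else:
        assigned = [ind.stock if ind.stock else "admixed" for ind in panel.individuals]
    counts: dict[tuple[str, int], dict[str, int]] = {}
    for s, yr, a in zip(seasons, years, assigned):
        if s == "unknown" or yr is None:
            continue
        cell = counts.setdefault((s, int(yr)), {})
        cell[a] = cell.get(a, 0) + 1
    cells: dict[tuple[str, int], dict[str, float]] = {}
    for key, cell in counts.items():
        named = {k: v for k, v in cell.items() if k != "admixed"}
        total = sum(named.values())
        cells[key] = {k: 100.0 * v / total for k, v in named.items()} if total else {}
    return SeasonComposition(cells, counts, q_threshold)
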
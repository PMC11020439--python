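"""Per-locus and per-population diversity statistics.

Expected heterozygosity uses Nei's unbiased small-sample form
``(2n/(2n-1)) * (1 - sum p_i^2)``; PIC is Botstein's marker-informativeness
index; Fis is the Weir-Cockerham single-population ANOVA estimator with
permutation significance (alleles shuffled among individuals within the
population, which preserves allele frequencies and breaks heterozygote
deficits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel

__all__ = [
    "LocusDiversity",
    "allele_frequencies",
    "locus_diversity",
    "multilocus_summary",
    "null_allele_frequency",
]


@dataclass
class LocusDiversity:
    """One row of a per-locus, per-population diversity table."""

    locus: str
    population: str
    n: int
    na: int
    ho: float
    he: float
    pic: float
    fis: float | None       # None when undefined (monomorphic locus)
    p_hwe: float | None = None
    null_freq: float | None = None
    null_suspect: bool = False


def _pop_indices(panel: GenotypePanel, population: str | None, by: str) -> np.ndarray | None:
    if population is None or population == "all":
        return None
    groups = panel.group_indices(by)
    if population not in groups:
        raise KeyError(f"no population {population!r} under grouping {by!r}")
    return groups[population]


def allele_frequencies(
    panel: GenotypePanel,
    locus: str,
    population: str | None = None,
    by: str = "section",
) -> dict[int, float]:
    """Sample allele frequencies over the 2n non-missing gene copies at a locus."""
    idx = _pop_indices(panel, population, by)
    g = panel.genotypes(locus, idx)
    if g.size == 0:
        raise ValueError(f"no genotype data at locus {locus} in population {population}")
    alleles, counts = np.unique(g, return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def _wc_single_pop_components(g: np.ndarray) -> tuple[float, float]:
    """Weir-Cockerham within-population variance components (b, c) summed over alleles.

    b: between individuals within the population; c: within individuals.
    The single-population inbreeding estimator is f = 1 - sum(c)/sum(b+c).
    """
    n = g.shape[0]
    alleles = np.unique(g)
    het = g[:, 0] != g[:, 1]
    b_sum = c_sum = 0.0
    for a in alleles:
        dose = (g == a).sum(axis=1)
        p = dose.mean() / 2.0
        h = float(np.mean((dose == 1) & het)) if het.any() else 0.0
        # h is the frequency of heterozygotes carrying exactly one copy of a
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
        c = h / 2.0
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def _ho_he_pic(g: np.ndarray) -> tuple[float, float, float, int]:
    n = g.shape[0]
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    _, counts = np.unique(g, return_counts=True)
    p = counts / (2.0 * n)
    sum_p2 = float(np.sum(p**2))
    he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - sum_p2) if n > 0 else 0.0
    # PIC: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
    cross = (np.sum(p**2) ** 2 - np.sum(p**4)) / 2.0
    pic = 1.0 - sum_p2 - 2.0 * cross
    return ho, he, pic, len(counts)


def locus_diversity(
    panel: GenotypePanel,
    locus: str,
    population: str | None = None,
    by: str = "section",
    unbiased: bool = True,
) -> LocusDiversity:
    """Na, Ho, He, PIC and Fis for one locus in one population."""
    idx = _pop_indices(panel, population, by)
    g = panel.genotypes(locus, idx)
    n = g.shape[0]
    if n < 1:
        raise ValueError(f"no genotypes at {locus} in {population}")
    ho, he, pic, na = _ho_he_pic(g)
    if not unbiased:
        he *= (2.0 * n - 1.0) / (2.0 * n)
    if na == 1:
        return LocusDiversity(locus, population or "all", n, 1, 0.0, 0.0, 0.0, fis=None)
    if n < 2:
        return LocusDiversity(locus, population or "all", n, na, ho, he, pic, fis=None)
    b, c = _wc_single_pop_components(g)
    fis = 1.0 - c / (b + c) if (b + c) > 0 else None
    d = LocusDiversity(locus, population or "all", n, na, ho, he, pic, fis)
    if he > 0:
        d.null_freq, d.null_suspect = null_allele_frequency(ho, he)
    return d


@dataclass
class MultilocusSummary:
    population: str
    n_loci: int
    mean_na: float
    mean_ho: float
    mean_he: float
    fis: float | None
    p_fis: float | None
    per_locus: list[LocusDiversity]


def multilocus_summary(
    panel: GenotypePanel,
    population: str | None = None,
    by: str = "section",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> MultilocusSummary:
    """Across-loci means plus the multilocus Weir-Cockerham Fis with permutation p.

    The multilocus Fis is the ratio of summed variance components across loci,
    not the mean of per-locus ratios.  One-tailed significance (Fis > 0) is
    obtained by shuffling the 2n gene copies among individuals within the
    population, locus by locus.
    """
    if panel.n_loci < 2:
        raise ValueError("multilocus summary needs at least 2 loci")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    idx = _pop_indices(panel, population, by)
    rows = [locus_diversity(panel, loc.name, population, by) for loc in panel.loci]
    genos = [panel.genotypes(loc.name, idx) for loc in panel.loci]
    genos = [g for g in genos if g.shape[0] >= 2 and len(np.unique(g)) > 1]

    def multilocus_f(gs: list[np.ndarray]) -> float | None:
        B = C = 0.0
        for g in gs:
            b, c = _wc_single_pop_components(g)
            B += b
            C += c
        return 1.0 - C / (B + C) if (B + C) > 0 else None

    fis_obs = multilocus_f(genos) if genos else None
    p_val = None
    if fis_obs is not None:
        rng = np.random.default_rng(seed)
        exceed = 0
        flats = [g.ravel().copy() for g in genos]
        for _ in range(n_permutations):
            perm = []
            for flat in flats:
                shuffled = rng.permutation(flat)
                perm.append(np.sort(shuffled.reshape(-1, 2), axis=1))
            f = multilocus_f(perm)
            if f is not None and f >= fis_obs:
                exceed += 1
        p_val = (1.0 + exceed) / (n_permutations + 1.0)
    return MultilocusSummary(
        population=population or "all",
        n_loci=len(rows),
        mean_na=float(np.mean([r.na for r in rows])),
        mean_ho=float(np.mean([r.ho for r in rows])),
        mean_he=float(np.mean([r.he for r in rows])),
        fis=fis_obs,
        p_fis=p_val,
        per_locus=rows,
    )


def null_allele_frequency(ho: float, he: float, suspect_threshold: float = 0.2) -> tuple[float, bool]:
    """Chakraborty homozygote-excess null-allele index r = (He - Ho)/(He + Ho).

    Clipped to [0, 1]; the flag marks loci whose estimate exceeds the suspect
    threshold (default 0.2), the screening used to discard null-ridden loci.
    """
    if he <= 0:
        raise ValueError("null-allele index undefined for He = 0")
    r = (he - ho) / (he + ho)
    r = float(np.clip(r, 0.0, 1.0))
    return r, r > suspect_threshold
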
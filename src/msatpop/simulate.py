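"""Synthetic genotype panels emulating the study design, plus a forward
Wright-Fisher simulator for validating the Ne and bottleneck machinery.

The panel generator draws ancestral allele frequencies from a symmetric
Dirichlet, diverges two stocks with a Balding-Nichols-style Dirichlet whose
concentration (1 - Fst)/Fst * p gives a closed-form expected Fst, assigns
stock membership by season (the rainy catch is dominated by one stock, the
dry catch by the other), and introduces inbreeding by drawing the second
gene copy identical-by-descent with probability Fis.

Defaults mirror the study conditions: 324 fish, 14 tri/tetranucleotide loci
with 9-35 alleles each, five river sections, weak stock divergence and
Fis around 0.07.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import GenotypePanel, Individual, Locus

__all__ = ["SimConfig", "WrightFisherConfig", "simulate_panel", "simulate_wright_fisher"]

# per-section sample sizes inferred from the study's per-section heterozygote
# fractions, rescaled to the 324 genotyped fish
_DEFAULT_SECTIONS = {"S4": 53, "S5": 55, "S6": 90, "S7": 43, "S8": 83}

_DEFAULT_SEASON_MIXTURE = {
    "rainy": {"Stock1": 0.08, "Stock2": 0.92},
    "dry": {"Stock1": 0.65, "Stock2": 0.35},
}


@dataclass
class SimConfig:
    n_individuals: int = 324
    n_loci: int = 14
    alleles_per_locus: tuple[int, int] = (9, 35)
    motif_length: int = 4
    ancestral_dirichlet_concentration: float = 1.0
    stock_divergence_fst: float = 0.005
    fis: float = 0.07
    section_sizes: Mapping[str, int] | None = None
    season_mixture: Mapping[str, Mapping[str, float]] | None = None
    years: tuple[int, ...] = (2020, 2021)
    null_allele_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.section_sizes is None:
            sizes = _scale_sections(_DEFAULT_SECTIONS, self.n_individuals)
            self.section_sizes = sizes
        if self.season_mixture is None:
            self.season_mixture = {k: dict(v) for k, v in _DEFAULT_SEASON_MIXTURE.items()}
        for season, mix in self.season_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"season {season!r} stock proportions must sum to 1")
        for rate in (self.stock_divergence_fst, self.fis, self.null_allele_rate, self.missing_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if sum(self.section_sizes.values()) != self.n_individuals:
            raise ValueError("section sizes must sum to n_individuals")
        lo, hi = self.alleles_per_locus
        if not 2 <= lo <= hi:
            raise ValueError("alleles_per_locus range must satisfy 2 <= lo <= hi")


def _scale_sections(proportions: Mapping[str, int], total: int) -> dict[str, int]:
    weight = sum(proportions.values())
    raw = {k: total * v / weight for k, v in proportions.items()}
    sizes = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = total - sum(sizes.values())
    for k in sorted(raw, key=lambda k: raw[k] - sizes[k], reverse=True)[:rem]:
        sizes[k] += 1
    return sizes


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated panel."""

    stocks: list[str]
    stock_freqs: dict[str, list[np.ndarray]]  # stock -> per-locus frequency vectors
    allele_sizes: list[np.ndarray]            # per-locus size ladders (bp)
    null_freq: dict[str, float] = field(default_factory=dict)


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a two-stock, seasonally mixed genotype panel under the configured design."""
    ss = np.random.SeedSequence(config.seed)
    r_freq, r_assign, r_geno, r_missing = [np.random.default_rng(s) for s in ss.spawn(4)]

    lo, hi = config.alleles_per_locus
    stocks = ("Stock1", "Stock2")
    loci: list[Locus] = []
    ladders: list[np.ndarray] = []
    freqs: dict[str, list[np.ndarray]] = {s: [] for s in stocks}
    fst = config.stock_divergence_fst
    for j in range(config.n_loci):
        k = int(r_freq.integers(lo, hi + 1))
        if k < 2:
            raise ValueError("infeasible allele range")
        start = int(r_freq.integers(100, 451 - k * config.motif_length))
        ladder = start + config.motif_length * np.arange(k)
        ladders.append(ladder)
        loci.append(Locus(f"L{j + 1:02d}", config.motif_length))
        anc = r_freq.dirichlet(np.full(k, config.ancestral_dirichlet_concentration))
        anc = np.clip(anc, 1e-6, None)
        anc /= anc.sum()
        for s in stocks:
            if fst > 0:
                conc = anc * (1.0 - fst) / fst
                freqs[s].append(r_freq.dirichlet(conc))
            else:
                freqs[s].append(anc.copy())

    # stock membership from the season mixture; seasons balanced per section
    individuals: list[Individual] = []
    stock_labels: list[str] = []
    i = 0
    for section, size in config.section_sizes.items():
        for m in range(size):
            season = "rainy" if m % 2 == 0 else "dry"
            year = int(config.years[(m // 2) % len(config.years)])
            mix = config.season_mixture[season]
            labels, probs = zip(*sorted(mix.items()))
            stock = str(r_assign.choice(labels, p=probs))
            individuals.append(Individual(f"ind{i:04d}", section, season, year, stock=None))
            stock_labels.append(stock)
            i += 1

    n = len(individuals)
    calls = np.zeros((n, config.n_loci, 2), dtype=np.int32)
    truth = SimTruth(stock_labels, freqs, ladders)
    for j in range(config.n_loci):
        k = len(ladders[j])
        has_null = config.null_allele_rate > 0
        for s_idx, s in enumerate(stocks):
            rows = np.flatnonzero(np.array(stock_labels) == s)
            p = freqs[s][j]
            if has_null:
                nu = config.null_allele_rate
                p_ext = np.concatenate([(1 - nu) * p, [nu]])  # last slot = null allele
            else:
                p_ext = p
            m = len(rows)
            first = r_geno.choice(len(p_ext), size=m, p=p_ext)
            ibd = r_geno.random(m) < config.fis
            second = np.where(
                ibd, first, r_geno.choice(len(p_ext), size=m, p=p_ext)
            )
            a = np.empty((m, 2), dtype=np.int64)
            null_code = len(p)  # index of the hidden allele
            for col, draw in ((0, first), (1, second)):
                a[:, col] = draw
            sizes = np.empty((m, 2), dtype=np.int32)
            for col in (0, 1):
                visible = a[:, col] < len(p)
                sizes[visible, col] = ladders[j][a[visible, col]]
            both_null = (a[:, 0] == null_code) & (a[:, 1] == null_code)
            one_null = ((a[:, 0] == null_code) ^ (a[:, 1] == null_code)) & ~both_null
            if has_null:
                # null heterozygote looks like a homozygote for the visible allele
                vis_col = np.where(a[:, 0] == null_code, 1, 0)
                for row_i in np.flatnonzero(one_null):
                    v = sizes[row_i, vis_col[row_i]]
                    sizes[row_i, 0] = sizes[row_i, 1] = v
                sizes[both_null] = -1
            calls[rows, j, :] = sizes
        if has_null:
            truth.null_freq[loci[j].name] = config.null_allele_rate
    if config.missing_rate > 0:
        drop = r_missing.random((n, config.n_loci)) < config.missing_rate
        calls[drop] = -1
    panel = GenotypePanel(loci, individuals, calls)
    return panel, truth


# ------------------------------------------------------------- Wright-Fisher
@dataclass
class WrightFisherConfig:
    true_ne: int = 100
    n_loci: int = 20
    n_generations: int = 200
    mutation_rate: float = 1e-3
    mutation_model: str = "SMM"          # IAM | SMM | TPM
    tpm_p_single_step: float = 0.70
    tpm_multistep_variance: float = 30.0
    sample_size: int = 50
    motif_length: int = 4
    initial_repeats: int = 25
    size_schedule: Sequence[tuple[int, int]] | None = None  # (from_generation, diploid size)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ne < 2:
            raise ValueError("true_ne must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.sample_size > self.true_ne and self.size_schedule is None:
            raise ValueError("sample_size cannot exceed the (final) population size")
        if self.mutation_model not in ("IAM", "SMM", "TPM"):
            raise ValueError(f"unknown mutation model {self.mutation_model!r}")


def _sizes_by_generation(config: WrightFisherConfig) -> np.ndarray:
    sizes = np.full(config.n_generations, config.true_ne, dtype=np.int64)
    if config.size_schedule:
        for start, size in sorted(config.size_schedule):
            sizes[start:] = size
    if config.sample_size > sizes[-1]:
        raise ValueError("sample_size cannot exceed the final population size")
    return sizes


def simulate_wright_fisher(config: WrightFisherConfig) -> GenotypePanel:
    """Forward diploid Wright-Fisher simulation of unlinked microsatellites.

    Random mating with free recombination: each offspring draws two parents;
    each transmitted gamete picks one of the parent's two gene copies per
    locus independently.  Allele states are repeat counts, reported as
    fragment sizes 100 + motif * repeats.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _sizes_by_generation(config)
    n = int(sizes[0])
    L = config.n_loci
    pop = np.full((n, L, 2), config.initial_repeats, dtype=np.int64)
    if config.mutation_model == "TPM":
        v = config.tpm_multistep_variance
        q_geom = (-1.0 + np.sqrt(1.0 + 4.0 * v)) / (2.0 * v)
    iam_counter = 10_000  # fresh states outside the stepwise ladder
    for gen in range(1, config.n_generations):
        n_next = int(sizes[gen])
        mothers = rng.integers(0, n, size=n_next)
        fathers = rng.integers(0, n, size=n_next)
        m_side = rng.integers(0, 2, size=(n_next, L))
        f_side = rng.integers(0, 2, size=(n_next, L))
        nxt = np.empty((n_next, L, 2), dtype=np.int64)
        nxt[:, :, 0] = pop[mothers[:, None], np.arange(L)[None, :], m_side]
        nxt[:, :, 1] = pop[fathers[:, None], np.arange(L)[None, :], f_side]
        n_mut = rng.poisson(config.mutation_rate * n_next * L * 2)
        if n_mut:
            ii = rng.integers(0, n_next, size=n_mut)
            jj = rng.integers(0, L, size=n_mut)
            cc = rng.integers(0, 2, size=n_mut)
            if config.mutation_model == "IAM":
                for t in range(n_mut):
                    nxt[ii[t], jj[t], cc[t]] = iam_counter
                    iam_counter += 1
            elif config.mutation_model == "SMM":
                steps = rng.choice([-1, 1], size=n_mut)
                nxt[ii, jj, cc] += steps
            else:
                single = rng.random(n_mut) < config.tpm_p_single_step
                mags = np.where(single, 1, rng.geometric(q_geom, size=n_mut))
                signs = rng.choice([-1, 1], size=n_mut)
                nxt[ii, jj, cc] += mags * signs
        pop = nxt
        n = n_next
    pick = rng.choice(n, size=config.sample_size, replace=False)
    repeats = pop[pick]
    repeats = np.maximum(repeats, 1)  # reflect unrealistic non-positive ladders
    calls = (100 + config.motif_length * repeats).astype(np.int32)
    loci = [Locus(f"wf{j + 1:02d}", config.motif_length) for j in range(L)]
    individuals = [Individual(f"wf{i:04d}", section="wf") for i in range(config.sample_size)]
    return GenotypePanel(loci, individuals, calls)


def monomorphic_fraction(panel: GenotypePanel) -> float:
    """Convenience: fraction of loci with a single observed allele."""
    mono = 0
    for loc in panel.loci:
        if len(np.unique(panel.genotypes(loc.name))) == 1:
            mono += 1
    return mono / panel.n_loci
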
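# Methods

This note documents the models behind each estimator, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical conventions at the edges.

## Data model

A `GenotypePanel` stores diploid genotypes as integer fragment sizes in base
pairs (the raw output of fragment analysis), shape `(individuals, loci, 2)`,
pairs canonicalized smaller-first, missing cells `(-1, -1)`. Sizes rather
than opaque codes are load-bearing: the M-ratio needs true allele-size
ladders. GenePop's 3-digit-code constraint is bridged by rank-encoding plus
a JSON sidecar (code→size, motif lengths, individual metadata), so a
GenePop round trip is lossless; the STRUCTURE dialect cannot carry section
names or motifs, so a STRUCTURE round trip preserves loci and calls but
reduces section labels to integer codes. Half-calls are rejected at parse
time — a cell is complete or missing.

Populations are groupings over individual metadata (section, season, stock,
year); all statistics take the grouping as a parameter, matching a design in
which the same fish are analyzed by river section, by inferred stock and by
season.

## Diversity and inbreeding

Expected heterozygosity uses Nei's unbiased small-sample estimator
`He = (2n/(2n-1))(1 - Σ p_i²)` (disable with `unbiased=False`). PIC is
`1 - Σ p_i² - Σ_{i<j} 2 p_i² p_j²`. The per-population inbreeding
coefficient is the Weir–Cockerham within-population ANOVA estimator,
`f = 1 - Σc / Σ(b+c)` with per-allele components

    b = n/(n-1) [ p(1-p) - (2n-1)/(4n) h ],   c = h/2,

where `h` is the frequency of heterozygotes carrying the allele. This `f`
is exactly zero when Ho equals unbiased He, so it agrees with the intuitive
`1 - Ho/He` at the null while behaving better at small n. The multilocus
Fis is the ratio of summed components (not the mean of ratios); significance
comes from shuffling the 2n gene copies among individuals within the
population per locus (one-tailed for heterozygote deficit), which holds
allele frequencies fixed and breaks only the within-individual pairing.
Missing data are handled by pairwise deletion per locus; listwise deletion
would discard most individuals at 14 loci.

The null-allele screen is Chakraborty's homozygote-excess index
`r = (He-Ho)/(He+Ho)` clipped to [0, 1], flagged above 0.2 — the screening
level at which loci were discarded in the motivating study design.

## Exact Hardy–Weinberg and linkage tests

The HWE test conditions on allele counts. For ≤ 3 alleles and ≤ 30
individuals every genotype table is enumerated and the p-value is the
cumulative conditional probability of tables no more probable than the
observed one (probability ordering, not a statistic). Larger tables use a
switch Markov chain on the 2n gene copies: two copies are transposed between
individuals each step. The uniform distribution over copy pairings induces
exactly the HWE conditional distribution on tables, so every switch is
accepted and the p-value is the post-dememorization visit fraction of
less-probable tables; the log table probability is maintained incrementally.
Defaults are 1,000,000 steps with 100,000 dememorization (the common chain
lengths for this test); the type-I calibration in the test suite uses
shorter chains with the chain-length noted there.

The genotypic LD test builds the two-locus genotype contingency table,
computes the log-likelihood G statistic, and permutes one locus's genotypes
among individuals (which preserves both margins); `p = (1+#{G* ≥ G})/(B+1)`.
Holm's step-down correction implements "sequential Bonferroni"; across-locus
combination uses Fisher's `X² = -2 Σ ln p` with 2m df, with zero p-values
clamped to the machine minimum and flagged (a permutation-based global
alternative is the per-population permutation Fis test).

## Bottleneck tests

For each polymorphic locus the equilibrium heterozygosity distribution given
the observed allele count k is simulated: a Kingman coalescent genealogy of
the 2n sampled genes, mutations Poisson on branches at rate θ/2 per unit
coalescent time, allele states propagated root-to-leaves, replicates kept
only when they realize exactly k alleles. θ is set so the expected allele
count is k: the closed form `E[K] = Σ θ/(θ+i)` under IAM, bisection on
pilot simulations for SMM/TPM (size homoplasy has no closed form). Under
IAM the accepted-replicate distribution is θ-free (Ewens sampling formula
conditioned on k), which the test suite exploits as an exhaustive
enumeration oracle at small n.

Mutation models: IAM (every mutation a fresh allele — only the most recent
mutation on a leaf's root-path matters, so a branch-level shortcut is
exact), SMM (±1 repeat; only the per-branch net displacement matters,
sampled in closed form), TPM (single-step with probability 0.70, otherwise
a geometric multi-step with variance 30 — the conventional two-phase
defaults, exposed in `MutationModel` because the TPM p-values depend on
them). The model ordering of equilibrium heterozygosity at fixed (n, k) is
IAM < TPM < SMM; this is why the IAM test is the most sensitive to excess
and the SMM test the most conservative, the pattern the seasonal-stock
study design shows.

`DH = (He_obs - mean Heq)/sd Heq` per locus; the one-tailed Wilcoxon
signed-rank test (exact null up to 25 loci, normal approximation above)
asks whether DH is centred above zero. Default 10,000 coalescent replicates
per locus, reduced in tests and the pipeline (sizes stated where used).

The modified Garza–Williamson index is `M = k/(r+1)` with
`r = (max - min)/motif` (floor division when an off-ladder allele makes the
span a non-multiple of the motif); monomorphic loci give M = 1 by the
degenerate-range convention. Population value: arithmetic mean over loci,
compared against the 0.68 criterion. The "overall" row of a report pools
all individuals (the default interpretation); a mean across populations is
available by averaging the per-population values.

## LD-method effective size

For every locus pair, over individuals typed at both loci: Burrows'
composite disequilibrium per allele pair,
`Δ̂ = n/(n-1) (mean(XY)/2 - 2 p̂ q̂)` with X, Y the diploid dosages, and
`r̂² = Δ̂²/(p(1-p) q(1-q))`. Alleles below the MAF cutoff (default 0.02,
the study's screening level) or masked by `filter_panel` are excluded —
masking affects only Ne estimation, never diversity statistics. r̂² values
are averaged with weights proportional to the shared sample size; the
sampling bias `E[r²|S]` (`1/S + 3.19/S²` for S ≥ 30, else
`0.0018 + 0.907/S + 4.44/S²`) is subtracted; Ne follows the random-mating
inversion `(1/3 + √(1/9 - 2.76 r²'))/(2 r²')` (0.308-variant below S = 30).
Non-positive r²' and negative discriminants report Ne = ∞ — with weak drift
signal this happens in roughly half of replicate samples, which is inherent
to an unbiased estimator, not a defect.

The 95% CI is a delete-one-locus block jackknife: all pairs containing one
locus are removed at a time, the weighted mean recomputed, and the
chi-square effective-df construction (`n' = 2 r̄⁴/Var_jack`) maps the CI
through the Ne inversion. Deleting single locus *pairs* instead understates
the variance because pairs sharing a locus are correlated; measured
coverage at true Ne = 100 (S = 50, 20 loci) was ~85% for pair deletion and
~94% for locus deletion, so the block form is the default and the
calibration test asserts ≥ 17/20 coverage.

For projection, the Ne is the point estimate when finite, otherwise the
lower CI bound (the convention needed when the point estimate is infinite
but the data still bound Ne from below). `Ht/H0 = (1 - 1/(2Ne))^t` gives
the retained heterozygosity; the threat rule is ≥ 25% reduction at t = 10
(critically endangered), t = 50 (endangered), t = 100 (vulnerable), else
non-threatened, with an inclusive boundary ("reached" 25% triggers).

## Differentiation

Weir–Cockerham θ sums the (a, b, c) variance components over alleles and
loci; populations with fewer than two typed individuals are excluded.
F′ST = θ/θ_max where θ_max recodes each population's alleles to disjoint
sets while keeping genotype structure — the recoding method of
standardization; permutation significance shuffles individuals among
populations (default 999, matching P = 0.001 granularity). Note that
standardization scales sampling noise too: for negative θ (no
differentiation) F′ST is also negative and the F′ST ≥ θ dominance holds for
θ ≥ 0.

Jost's DEST per locus uses the sample-size-corrected
`Hs = (2ñ/(2ñ-1))(1 - mean Σ p²)` with ñ the harmonic mean sample size,
`Ht = 1 - Σ p̄² + Hs/(2ñr)`, and `D = (r/(r-1))(Ht-Hs)/(1-Hs)`. The
multilocus value uses the transformed (1/D - 1) averaging; per-locus D is
reported unclipped, but values ≤ 0 are floored at 1e-9 inside the transform
(documented limitation: a few near-zero loci dominate the harmonic form,
which is the known behaviour of this aggregation).

AMOVA works at the gene-copy level with 0/1 allele-identity distances: sums
of squares from within- and total-group pair counts, variance components by
the standard moment equations, Φ_ST = σ²_among/σ²_total (reported raw, and
floored at zero in the summary view), significance by permuting individuals
(both copies together) among groups. Degrees of freedom: among = g-1,
within = 2N-g, total = 2N-1; report lines print (g-1, 2N-1) as
(among, total).

The exact G-test of allele-frequency heterogeneity runs a Metropolis chain
over contingency tables with fixed margins (hypergeometric target, swap
moves), p = visit fraction with G ≥ G_obs, batch-based standard error;
defaults 10,000 dememorization and 100 batches × 5,000 iterations,
configurable down. The global test combines per-locus p-values by Fisher's
method, flooring MCMC zeros at 1/iterations.

## Stock inference

The admixture-model Gibbs sampler carries a latent cluster per gene copy:
per sweep it draws cluster allele frequencies from Dirichlet(1 + counts),
individual membership vectors from Dirichlet(α + copy counts), then
reassigns copies; the mean post-burn-in data log-likelihood is L(K) and the
posterior-mean Q is returned. Missing copies are skipped. α is fixed at 1.0
in a single run by default; `sample_alpha=True` gives α a Uniform(0, 10)
prior with a Metropolis step, and the ensemble layer `run_k_grid` turns this
on by default — with α pinned at 1 the membership prior is too flat for
ghost clusters to empty at K above the truth, which breaks the
membership-based K estimators (the standard protocol also infers α).
Single-run defaults are 50,000 sweeps / 10,000 burn-in; examples, tests and
the acceptance script use 200–1,500 sweeps at n = 80–300 and 6–14 loci,
where the likelihood trace plateaus within ~50 sweeps; a split-half trace
check flags non-convergence without failing the run.

ΔK is the Evanno second difference `|L(K+1) - 2L(K) + L(K-1)|/sd(L(K))`
over replicate means, undefined (NaN, flagged) when the replicate sd is
zero. The four membership estimators count, per replicate, clusters whose
mean (or median) membership within at least one predefined group exceeds
the threshold (0.5); counts are summarized per K and the estimators take
the median/maximum of that profile across the K grid — the count plateaus
at the true K, and summarizing only the largest K undercounts when a real
cluster splits. Predefined groups default to river sections; for
seasonally mixed designs the seasons are the informative grouping and the
pipeline uses them when present. `chosen_k` is the modal agreement of ΔK's
argmax and the four estimators, ties resolved to the smaller K.

Replicate alignment maximizes Q-column agreement with the first replicate
per K via the Hungarian algorithm. DAPC one-hot-encodes allele dosages
(missing imputed at column means), reduces by PCA (component count fixed or
chosen by stratified cross-validation), and fits LDA; accuracy is the
cross-validated assignment rate. Season composition assigns each individual
to its argmax cluster when that membership is ≥ 0.5 and unique, else
"admixed" (excluded from percentages).

## Synthetic data

`simulate_panel` emulates the study design: ancestral allele frequencies
from a symmetric Dirichlet(1.0) on 9–35 alleles per locus (giving the
observed He range 0.76–0.96), two stocks diverged by a Balding–Nichols
Dirichlet with concentration `p(1-F)/F` so the expected FST equals the
target (verified by Monte-Carlo calibration: mean Weir–Cockerham θ = 0.050
at target 0.05 over 20 seeds), stock membership drawn per season (rainy 92%
Stock2, dry 65% Stock1 — the design's capture percentages treated as
sampling proportions), inbreeding by drawing the second gene copy
identical-by-descent with probability Fis, optional null alleles (a hidden
allele: null heterozygotes look homozygous, null homozygotes become
missing) and missing data. Section sizes default to the per-section sample
sizes implied by the study's heterozygote fractions, rescaled to 324. The
default divergence is weak (0.005), like the study's; the recovery
experiments use 0.05 where specified.

What the generator does *not* emulate: genuine geographic structure among
sections (sections are stock mixtures with no section-specific drift),
linkage, allele-size constraints (ladders are perfect arithmetic ladders, so
simulated M-ratios are near 1 and not comparable to real fragmented
ladders), genotyping error beyond null alleles, and family structure.
Passing recovery tests therefore demonstrate estimator correctness under
the model's assumptions, not robustness to real-data artefacts.

`simulate_wright_fisher` is an exact forward diploid simulator: each
offspring draws two parents, each gamete picks one of the parent's copies
per locus independently (free recombination), mutations per the chosen
model, size changes by a schedule of (generation, size) breakpoints. This
preserves the parent-sharing structure that creates the cross-locus LD the
Ne method reads, which gamete-pool shortcuts would destroy. Repeat counts
are floored at 1 before conversion to fragment sizes.

## Problem sizes used in validation

The shipped test suite and acceptance script run: LD-Ne calibration at
Ne = 100 with 20 loci, S = 50, 20 replicates; two-stock recovery at
n = 300, 14 loci, K = 1–4 with 3 replicates of 500 sweeps; type-I error of
the exact tests at 500–800 null replicates (HWE chains of 3,000 steps, LD
tests with 150 permutations); equilibrium-heterozygosity validation at
10,000 accepted replicates against exhaustive Ewens enumeration; bottleneck
power and M-ratio contrasts on 12–30 paired forward simulations. These
sizes give stable pass/fail behaviour at conventional tolerances while
keeping a full run in minutes on a single core.

## Known limitations

* The G-test chain and the HWE switch chain are serial Python loops; panels
  with hundreds of alleles per locus will be slow at the full default chain
  lengths.
* The LD-Ne bias constants are the published empirical fits; outside their
  fitted range (very small S, extreme allele-frequency skew) the correction
  degrades gracefully but is not re-fitted here.
* Jost's D multilocus aggregation is unstable when some loci have D ≈ 0;
  inspect the per-locus values it also returns.
* The admixture model assumes unlinked loci and independent allele
  frequencies between clusters; at very weak divergence a correlated-
  frequencies prior would be more sensitive.
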
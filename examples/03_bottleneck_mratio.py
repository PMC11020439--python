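"""Bottleneck detection: heterozygosity excess under IAM/SMM/TPM plus the
Garza-Williamson M-ratio, on a forward-simulated population crash.

A population held at Ne=100 crashes to 10 five generations before sampling.
After a crash, rare alleles vanish faster than gene diversity, so observed
He exceeds the equilibrium value implied by the surviving allele number
(heterozygosity excess, strongest under the infinite-alleles model), and the
allele-size ladder develops holes (low M-ratio, < 0.68 flags a reduction).
"""

from msatpop import (
    MutationModel,
    WrightFisherConfig,
    heterozygosity_excess_test,
    m_ratio_mean,
    simulate_wright_fisher,
)

base = dict(true_ne=100, n_loci=12, n_generations=260, mutation_rate=5e-3,
            mutation_model="SMM", sample_size=10)
crashed = simulate_wright_fisher(WrightFisherConfig(**base, size_schedule=[(255, 10)], seed=3))
control = simulate_wright_fisher(WrightFisherConfig(**base, seed=3))

for label, panel in (("crashed 100->10", crashed), ("constant Ne=100", control)):
    ps = {}
    for kind in ("IAM", "SMM", "TPM"):
        report = heterozygosity_excess_test(
            panel, model=MutationModel(kind), n_sim=400, seed=11
        )
        ps[kind] = getattr(report, f"p_{kind.lower()}")
    m, below = m_ratio_mean(panel)
    print(f"{label}: Wilcoxon one-tailed p IAM={ps['IAM']:.4f} "
          f"SMM={ps['SMM']:.4f} TPM={ps['TPM']:.4f}; "
          f"M-ratio={m:.3f}{' (< 0.68: reduction signal)' if below else ''}")

print("\nsmall IAM p in the crashed population = heterozygosity excess; "
      "the SMM test is conservative because stepwise equilibrium He is higher")
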
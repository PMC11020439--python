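"""End-to-end orchestration: configuration, seeded runs, and a study-report
bundle (diversity, HWE, bottleneck, Ne/projection, differentiation, stocks).

Every stochastic stage receives a substream of the global seed, and the seeds
are recorded in the results JSON so any stage can be reproduced in isolation.
Module failures are recorded in the bundle's error list; dependent stages are
skipped rather than silently dropped.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bottleneck import IAM, SMM, TPM, MutationModel, heterozygosity_excess_test, m_ratio_mean
from .diversity import multilocus_summary
from .hwe import hwe_exact, sequential_bonferroni
from .differentiation import amova, g_test_differentiation, pairwise_matrix
from .ne import (
    classify_threat,
    estimate_ne_ld,
    project_heterozygosity,
    select_ne_for_projection,
)
from .panel import read_panel
from .simulate import SimConfig, simulate_panel
from .stocks import run_k_grid, select_k, season_composition

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    input_path: str | None = None          # None -> simulate a demo panel
    input_format: str = "tabular"
    grouping: str = "section"
    seed: int = 0
    out_dir: str = "msatpop_report"
    # module knobs (desk-scale defaults; the study-scale values are larger)
    hwe_steps: int = 20_000
    hwe_dememorization: int = 2_000
    bottleneck_sims: int = 300
    ne_maf_cutoff: float = 0.02
    amova_permutations: int = 199
    gtest_batches: int = 20
    gtest_iters: int = 500
    gtest_dememorization: int = 1_000
    k_values: tuple[int, ...] = (1, 2, 3, 4)
    k_replicates: int = 3
    mcmc_steps: int = 1_500
    mcmc_burn_in: int = 500
    fis_permutations: int = 200
    sim_config: SimConfig | None = None


def _seed_stream(seed: int):
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        yield int(child.generate_state(1)[0] % (2**31))


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run every analysis stage and write a report bundle under ``out_dir``.

    Returns the machine-readable results dictionary (also written as
    ``results.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    results: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "errors": {},
    }

    # ---------------------------------------------------------------- input
    if config.input_path is not None:
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input panel not found: {path}")
        panel = read_panel(path, config.input_format)
    else:
        sim_seed = next(seeds)
        sim = config.sim_config or SimConfig(seed=sim_seed)
        results["stage_seeds"]["simulate"] = sim.seed
        panel, truth = simulate_panel(sim)
        panel = panel.with_stocks(truth.stocks)
    by = config.grouping
    groups = panel.group_indices(by)
    results["panel"] = {
        "n_individuals": panel.n_individuals,
        "n_loci": panel.n_loci,
        "grouping": by,
        "populations": {k: int(len(v)) for k, v in groups.items()},
    }

    # ------------------------------------------------------------ diversity
    try:
        rows = []
        fis_seed = next(seeds)
        results["stage_seeds"]["diversity"] = fis_seed
        for pop in groups:
            summary = multilocus_summary(
                panel, pop, by, n_permutations=config.fis_permutations, seed=fis_seed
            )
            for r in summary.per_locus:
                rows.append(vars(r))
            rows.append(
                {
                    "locus": "across_loci",
                    "population": pop,
                    "n": int(len(groups[pop])),
                    "na": summary.mean_na,
                    "ho": summary.mean_ho,
                    "he": summary.mean_he,
                    "fis": summary.fis,
                    "p_hwe": None,
                    "null_freq": None,
                    "null_suspect": None,
                }
            )
            results.setdefault("diversity", {})[pop] = {
                "mean_na": summary.mean_na,
                "mean_ho": summary.mean_ho,
                "mean_he": summary.mean_he,
                "fis": summary.fis,
                "p_fis": summary.p_fis,
            }
        pd.DataFrame(rows).to_csv(out / "diversity.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - recorded, not silenced
        results["errors"]["diversity"] = repr(exc)

    # ----------------------------------------------------------------- HWE
    try:
        hwe_seed = next(seeds)
        results["stage_seeds"]["hwe"] = hwe_seed
        hwe_rows = []
        for pop in groups:
            pvals, keys = [], []
            for loc in panel.loci:
                res = hwe_exact(
                    panel, loc.name, pop, by,
                    steps=config.hwe_steps,
                    dememorization=config.hwe_dememorization,
                    seed=hwe_seed,
                )
                pvals.append(res.p_value)
                keys.append(loc.name)
            flags = sequential_bonferroni(pvals)
            for name, p, f in zip(keys, pvals, flags):
                hwe_rows.append({"population": pop, "locus": name, "p_hwe": p, "holm_significant": f})
        pd.DataFrame(hwe_rows).to_csv(out / "hwe.csv", index=False)
        results["hwe"] = {
            "n_tests": len(hwe_rows),
            "n_holm_significant": int(sum(r["holm_significant"] for r in hwe_rows)),
        }
    except Exception as exc:
        results["errors"]["hwe"] = repr(exc)

    # ------------------------------------------------------------ bottleneck
    try:
        bn_seed = next(seeds)
        results["stage_seeds"]["bottleneck"] = bn_seed
        bn_rows = []
        for pop in groups:
            row: dict[str, Any] = {"population": pop}
            for model in (MutationModel(IAM), MutationModel(SMM), MutationModel(TPM)):
                rep = heterozygosity_excess_test(
                    panel, pop, by, model, n_sim=config.bottleneck_sims, seed=bn_seed
                )
                row[f"p_{model.kind.lower()}"] = getattr(rep, f"p_{model.kind.lower()}")
            m, below = m_ratio_mean(panel, pop, by)
            row["m_ratio"] = m
            row["m_below_0.68"] = below
            bn_rows.append(row)
        pd.DataFrame(bn_rows).to_csv(out / "bottleneck.csv", index=False)
        results["bottleneck"] = bn_rows
    except Exception as exc:
        results["errors"]["bottleneck"] = repr(exc)

    # -------------------------------------------------------- Ne + projection
    try:
        ne_rows = []
        for pop in groups:
            est = estimate_ne_ld(panel, pop, by, maf_cutoff=config.ne_maf_cutoff)
            row = {
                "population": pop,
                "ne_point": est.ne_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_pairs": est.n_pairs,
                "harmonic_n": est.harmonic_sample_size,
            }
            try:
                ne_used = select_ne_for_projection(est)
                proj = project_heterozygosity(ne_used, [10, 50, 100], pop)
                cls = classify_threat(proj)
                row.update(
                    ne_used=ne_used,
                    threat_class=cls,
                    **{f"reduction_pct_t{t}": p for t, p in zip(proj.horizons, proj.ht_reduction_pct)},
                )
            except ValueError as exc:
                row["projection_error"] = str(exc)
            ne_rows.append(row)
        pd.DataFrame(ne_rows).to_csv(out / "ne_projection.csv", index=False)
        results["ne"] = ne_rows
    except Exception as exc:
        results["errors"]["ne"] = repr(exc)

    # -------------------------------------------------------- differentiation
    try:
        diff_seed = next(seeds)
        results["stage_seeds"]["differentiation"] = diff_seed
        fst_m = pairwise_matrix(panel, "fst_standardized", by, n_permutations=0)
        dest_m = pairwise_matrix(panel, "jost_dest", by)
        labels = fst_m.labels
        combined = pd.DataFrame(
            np.triu(dest_m.values, 1) + np.tril(fst_m.values, -1),
            index=labels,
            columns=labels,
        )
        combined.to_csv(out / "pairwise_fstp_dest.csv")
        am = amova(panel, by, n_permutations=config.amova_permutations, seed=diff_seed)
        per_locus_g, global_g = g_test_differentiation(
            panel, by=by,
            dememorization=config.gtest_dememorization,
            batches=config.gtest_batches,
            iters_per_batch=config.gtest_iters,
            seed=diff_seed,
        )
        results["differentiation"] = {
            "amova": {
                "phi_st": am.phi_st,
                "df": [am.df_among, am.df_within, am.df_total],
                "p": am.p_value,
            },
            "g_test_global_p": global_g.p_value,
            "pairwise_labels": labels,
        }
    except Exception as exc:
        results["errors"]["differentiation"] = repr(exc)

    # ----------------------------------------------------------------- stocks
    try:
        stocks_seed = next(seeds)
        results["stage_seeds"]["stocks"] = stocks_seed
        ens = run_k_grid(
            panel,
            list(config.k_values),
            replicates=config.k_replicates,
            steps=config.mcmc_steps,
            burn_in=config.mcmc_burn_in,
            seed=stocks_seed,
        )
        has_seasons = any(ind.season != "unknown" for ind in panel.individuals)
        sel = select_k(ens, panel, group_by="season" if has_seasons else by)
        best = max(ens.at_k(sel.chosen_k), key=lambda r: r.log_likelihood)
        comp = None
        if any(ind.season != "unknown" for ind in panel.individuals) and sel.chosen_k > 1:
            comp = season_composition(panel, best.Q)
        pd.DataFrame(
            [
                {"K": r.K, "replicate": r.replicate, "log_likelihood": r.log_likelihood, "seed": r.seed}
                for r in ens.runs
            ]
        ).to_csv(out / "structure_runs.csv", index=False)
        np.savetxt(out / f"q_matrix_k{sel.chosen_k}.csv", best.Q, delimiter=",")
        results["stocks"] = {
            "chosen_k": sel.chosen_k,
            "delta_k": {str(k): v for k, v in sel.delta_k.items()},
            "estimators": {
                "med_mean_k": sel.med_mean_k,
                "max_mean_k": sel.max_mean_k,
                "med_med_k": sel.med_med_k,
                "max_med_k": sel.max_med_k,
            },
            "season_composition": (
                {f"{s}_{y}": cell for (s, y), cell in comp.cells.items()} if comp else None
            ),
        }
    except Exception as exc:
        results["errors"]["stocks"] = repr(exc)

    (out / "results.json").write_text(json.dumps(results, indent=1, default=_jsonable))
    with open(out / "run.log", "w") as fh:
        fh.write(f"msatpop {__version__} python {sys.version.split()[0]}\n")
        fh.write(f"seed {config.seed}\n")
        for stage, s in results["stage_seeds"].items():
            fh.write(f"stage {stage} seed {s}\n")
        for stage, err in results["errors"].items():
            fh.write(f"ERROR {stage}: {err}\n")
    return results


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(obj)}")
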
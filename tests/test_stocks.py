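"""Admixture-model clustering, K selection, alignment, DAPC, seasonal tables."""

import numpy as np
import pytest

from msatpop.stocks import (
    AdmixtureRun,
    QMatrixEnsemble,
    admixture_mcmc,
    align_replicates,
    dapc_lite,
    season_composition,
    select_k,
    _puechmaille_counts,
)
from msatpop.simulate import SimConfig, simulate_panel
from .conftest import make_panel


@pytest.fixture(scope="module")
def two_stock():
    cfg = SimConfig(
        n_individuals=150, n_loci=10, stock_divergence_fst=0.05, fis=0.0,
        section_sizes={"A": 75, "B": 75}, seed=7,
    )
    panel, truth = simulate_panel(cfg)
    return panel, truth


def test_k1_degenerate_q_and_likelihood(two_stock):
    panel, _ = two_stock
    run = admixture_mcmc(panel, K=1, steps=200, burn_in=50, seed=3)
    assert np.allclose(run.Q, 1.0)
    # L(1) ~ multinomial log-likelihood at the pooled frequencies
    from msatpop.diversity import allele_frequencies

    ll = 0.0
    for loc in panel.loci:
        freqs = allele_frequencies(panel, loc.name)
        g = panel.genotypes(loc.name)
        for a in g.ravel():
            ll += np.log(freqs[int(a)])
    assert run.log_likelihood == pytest.approx(ll, rel=0.02)


def test_same_seed_same_q(two_stock):
    panel, _ = two_stock
    r1 = admixture_mcmc(panel, K=2, steps=150, burn_in=50, seed=9)
    r2 = admixture_mcmc(panel, K=2, steps=150, burn_in=50, seed=9)
    assert np.array_equal(r1.Q, r2.Q)
    assert r1.log_likelihood == r2.log_likelihood


def test_q_rows_sum_to_one(two_stock):
    panel, _ = two_stock
    run = admixture_mcmc(panel, K=3, steps=150, burn_in=50, seed=2)
    assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)


def test_invalid_sampler_arguments(two_stock):
    panel, _ = two_stock
    with pytest.raises(ValueError):
        admixture_mcmc(panel, K=0, steps=10, burn_in=1)
    with pytest.raises(ValueError):
        admixture_mcmc(panel, K=2, steps=10, burn_in=10)


def test_membership_recovery_with_inferred_alpha(two_stock):
    """Divergence-0.05 stocks: most individuals get >= 0.8 membership in
    their true stock once the admixture concentration is inferred."""
    panel, truth = two_stock
    run = admixture_mcmc(panel, K=2, steps=800, burn_in=300, seed=5, sample_alpha=True)
    stocks = np.array(truth.stocks)
    q1 = run.Q[:, 0]
    col = 0 if np.mean((q1 > 0.5) == (stocks == "Stock1")) > 0.5 else 1
    member = np.where(stocks == "Stock1", run.Q[:, col], run.Q[:, 1 - col])
    assert np.mean(member >= 0.8) >= 0.9


# ------------------------------------------------------------------ alignment
def test_alignment_undoes_column_swap():
    rng = np.random.default_rng(0)
    q = rng.dirichlet(np.ones(3), size=40)
    ref = AdmixtureRun(3, 0, -10.0, q, 1)
    swapped = AdmixtureRun(3, 1, -10.0, q[:, [2, 0, 1]], 2)
    ens = align_replicates(QMatrixEnsemble([ref, swapped]))
    assert np.allclose(ens.runs[1].Q, q)


def test_alignment_k1_noop():
    q = np.ones((10, 1))
    ens = QMatrixEnsemble([AdmixtureRun(1, 0, -5.0, q, 1), AdmixtureRun(1, 1, -5.0, q, 2)])
    out = align_replicates(ens)
    assert np.allclose(out.runs[1].Q, q)


def test_aligned_replicates_are_stable(two_stock):
    panel, _ = two_stock
    runs = [
        admixture_mcmc(panel, K=2, steps=400, burn_in=150, seed=s, sample_alpha=True,
                       replicate=s)
        for s in range(4)
    ]
    aligned = align_replicates(QMatrixEnsemble(runs))
    qs = np.stack([r.Q for r in aligned.runs])
    per_individual_sd = qs.std(axis=0).mean()
    assert per_individual_sd < 0.05


# ------------------------------------------------------------------ select K
def _runs_with_l(mean_by_k, sd=1.0, reps=2, n=6, K_max=None):
    runs = []
    d = sd / np.sqrt(2)
    for K, mean in mean_by_k.items():
        for rep, delta in enumerate((-d, +d)[:reps]):
            q = np.full((n, K), 1.0 / K)
            runs.append(AdmixtureRun(K, rep, mean + delta, q, rep))
    return QMatrixEnsemble(runs)


def test_delta_k_hand_computation():
    # second difference at K=2: |-48 - 2(-50) + (-100)| = 48, at K=3: 1
    ens = _runs_with_l({1: -100.0, 2: -50.0, 3: -48.0, 4: -47.0}, sd=1.0)
    sel = select_k(ens)
    assert sel.delta_k[2] == pytest.approx(48.0, rel=1e-9)
    assert sel.delta_k[3] == pytest.approx(1.0, rel=1e-9)
    assert sel.chosen_k == 2


def test_delta_k_invariant_to_constant_shift():
    base = {1: -100.0, 2: -50.0, 3: -48.0, 4: -47.0}
    shifted = {k: v + 500.0 for k, v in base.items()}
    d1 = select_k(_runs_with_l(base)).delta_k
    d2 = select_k(_runs_with_l(shifted)).delta_k
    for k in d1:
        assert d1[k] == pytest.approx(d2[k])


def test_delta_k_zero_sd_flagged():
    ens = _runs_with_l({1: -10.0, 2: -5.0, 3: -4.0}, sd=0.0)
    sel = select_k(ens)
    assert np.isnan(sel.delta_k[2])


def test_puechmaille_floor_when_no_cluster_dominates():
    rng = np.random.default_rng(1)
    q = np.full((12, 3), 1 / 3) + rng.normal(0, 0.01, (12, 3))
    q = np.abs(q)
    q /= q.sum(axis=1, keepdims=True)
    runs = [AdmixtureRun(3, 0, -1.0, q, 0)]
    groups = {"A": np.arange(6), "B": np.arange(6, 12)}
    mean_counts, med_counts = _puechmaille_counts(runs, groups, threshold=0.5)
    assert mean_counts == [1] and med_counts == [1]


def test_puechmaille_invariant_to_relabeling():
    rng = np.random.default_rng(2)
    q = np.zeros((20, 2))
    q[:10, 0] = 0.9
    q[:10, 1] = 0.1
    q[10:, 0] = 0.2
    q[10:, 1] = 0.8
    groups = {"A": np.arange(10), "B": np.arange(10, 20)}
    runs = [AdmixtureRun(2, 0, -1.0, q, 0)]
    flipped = [AdmixtureRun(2, 0, -1.0, q[:, ::-1], 0)]
    assert _puechmaille_counts(runs, groups, 0.5) == _puechmaille_counts(flipped, groups, 0.5)


# ---------------------------------------------------------------------- DAPC
def test_dapc_separable_stocks_fully_assigned():
    calls = np.zeros((40, 3, 2), dtype=np.int32)
    calls[:20] = 100
    calls[20:] = 140
    panel = make_panel(calls)
    out = dapc_lite(panel, ["A"] * 20 + ["B"] * 20, n_pcs=3, seed=0)
    assert out["accuracy"] == 1.0


def test_dapc_random_labels_near_chance(two_stock):
    panel, _ = two_stock
    rng = np.random.default_rng(3)
    labels = list(rng.permutation(["A"] * 75 + ["B"] * 75))
    out = dapc_lite(panel, labels, n_pcs=20, seed=0)
    se = np.sqrt(0.25 / panel.n_individuals)
    assert abs(out["accuracy"] - 0.5) <= 4 * se


def test_dapc_recovers_weakly_diverged_stocks():
    cfg = SimConfig(n_individuals=300, n_loci=14, stock_divergence_fst=0.05,
                    fis=0.0, section_sizes={"A": 150, "B": 150}, seed=3)
    panel, truth = simulate_panel(cfg)
    out = dapc_lite(panel, truth.stocks, n_pcs="cv", seed=0)
    assert out["accuracy"] >= 0.8
    c1, c2 = out["centroids"].values()
    assert abs(c1[0] - c2[0]) > 0         # axis 1 separates the centroids


def test_dapc_overfitting_guard(two_stock):
    panel, truth = two_stock
    with pytest.raises(ValueError, match="n_pcs"):
        dapc_lite(panel, truth.stocks, n_pcs=10_000)


# ------------------------------------------------------------ season tables
def test_season_composition_all_one_stock():
    panel = make_panel(
        np.full((10, 2, 2), 100, dtype=np.int32),
        seasons=["rainy"] * 10, years=[2020] * 10,
    )
    q = np.tile([1.0, 0.0], (10, 1))
    comp = season_composition(panel, q)
    assert comp.cells[("rainy", 2020)] == {"Stock1": 100.0}


def test_season_composition_tie_is_admixed():
    panel = make_panel(
        np.full((2, 1, 2), 100, dtype=np.int32),
        seasons=["dry", "dry"], years=[2021, 2021],
    )
    q = np.array([[0.5, 0.5], [0.9, 0.1]])
    comp = season_composition(panel, q, q_threshold=0.5)
    assert comp.counts[("dry", 2021)]["admixed"] == 1
    assert comp.cells[("dry", 2021)] == {"Stock1": 100.0}


def test_season_composition_requires_metadata():
    panel = make_panel(np.full((4, 1, 2), 100, dtype=np.int32))
    with pytest.raises(ValueError, match="seasonal"):
        season_composition(panel, np.tile([1.0, 0.0], (4, 1)))
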
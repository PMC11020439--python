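"""Differentiation statistics against small-instance brute-force oracles."""

import numpy as np
import pytest

from msatpop.differentiation import (
    amova,
    fst_standardized,
    fst_weir_cockerham,
    g_test_differentiation,
    jost_dest,
    pairwise_matrix,
)
from msatpop.simulate import SimConfig, simulate_panel
from .conftest import make_panel


# ------------------------------------------------- Weir-Cockerham components
def wc_theta_oracle(geno_by_pop):
    """Independent implementation of the WC84 component algebra from explicit
    count formulas, written against the published estimator definitions."""
    pops = [np.asarray(g) for g in geno_by_pop]
    r = len(pops)
    ns = np.array([len(g) for g in pops], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for g in pops for row in g for a in row})
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([np.mean([row.tolist().count(al) for row in g]) / 2 for g in pops])
        h_i = np.array([np.mean([row.tolist().count(al) == 1 for row in g]) for g in pops])
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        A += nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        B += nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        C += hbar / 2
    return A / (A + B + C)


def test_theta_matches_component_oracle(rng):
    g1 = 100 + 4 * rng.choice(2, size=(5, 2), p=[0.7, 0.3])
    g2 = 100 + 4 * rng.choice(2, size=(5, 2), p=[0.3, 0.7])
    panel = make_panel(
        np.concatenate([g1, g2])[:, None, :], sections=["P1"] * 5 + ["P2"] * 5
    )
    theta, _ = fst_weir_cockerham(panel)
    assert theta == pytest.approx(wc_theta_oracle([g1, g2]), abs=1e-12)


def test_theta_null_two_identical_populations(two_pop_panel_factory):
    panel = two_pop_panel_factory([0.5, 0.3, 0.2], [0.5, 0.3, 0.2], 200, 200, seed=4)
    theta, _ = fst_weir_cockerham(panel)
    assert abs(theta) < 0.01


def test_theta_one_for_fixed_differences():
    calls = np.array([[[100, 100]]] * 6 + [[[104, 104]]] * 6)
    panel = make_panel(calls, sections=["P1"] * 6 + ["P2"] * 6)
    theta, _ = fst_weir_cockerham(panel)
    assert theta == pytest.approx(1.0)


# ------------------------------------------------------------------- F'ST
def test_fprime_saturates_on_disjoint_alleles():
    calls = np.array([[[100, 100]]] * 6 + [[[104, 104]]] * 6)
    panel = make_panel(calls, sections=["P1"] * 6 + ["P2"] * 6)
    fprime, _ = fst_standardized(panel)
    assert fprime == pytest.approx(1.0)


def test_fprime_near_zero_for_identical_populations(two_pop_panel_factory):
    panel = two_pop_panel_factory([0.4, 0.6], [0.4, 0.6], 150, 150, seed=9)
    fprime, _ = fst_standardized(panel)
    assert abs(fprime) < 0.02


def test_fprime_dominates_fst_on_random_panels():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        p1 = rng.dirichlet(np.ones(k))
        p2 = rng.dirichlet(np.ones(k))
        g1 = 100 + 4 * rng.choice(k, size=(25, 2), p=p1)
        g2 = 100 + 4 * rng.choice(k, size=(25, 2), p=p2)
        panel = make_panel(
            np.concatenate([g1, g2])[:, None, :], sections=["P1"] * 25 + ["P2"] * 25
        )
        theta, _ = fst_weir_cockerham(panel)
        fprime, _ = fst_standardized(panel)
        if theta >= 0:
            assert fprime >= theta - 1e-9
        else:
            # standardization scales the noise, it cannot change its sign
            assert fprime <= 0


# ------------------------------------------------------------------ Jost's D
def jost_d_oracle(freqs1, freqs2, n1, n2):
    """Direct evaluation of the two-population sample-size-corrected D."""
    n_harm = 2 / (1 / n1 + 1 / n2)
    hs_raw = 1 - (np.sum(np.square(freqs1)) + np.sum(np.square(freqs2))) / 2
    hs = (2 * n_harm / (2 * n_harm - 1)) * hs_raw
    pbar = (np.asarray(freqs1) + np.asarray(freqs2)) / 2
    ht = 1 - np.sum(pbar**2) + hs / (2 * n_harm * 2)
    return 2 * (ht - hs) / (1 - hs)


def test_jost_d_zero_for_identical_profiles():
    calls = np.concatenate(
        [np.tile([100, 104], (10, 1)), np.tile([100, 104], (10, 1))]
    )[:, None, :]
    panel = make_panel(calls, sections=["P1"] * 10 + ["P2"] * 10)
    d, _ = jost_dest(panel)
    assert d == pytest.approx(0.0, abs=1e-9)


def test_jost_d_one_for_disjoint_allele_sets():
    calls = np.array([[[100, 100]]] * 8 + [[[104, 104]]] * 8)
    panel = make_panel(calls, sections=["P1"] * 8 + ["P2"] * 8)
    d, _ = jost_dest(panel)
    assert d == pytest.approx(1.0, abs=1e-9)


def test_jost_d_matches_formula_oracle():
    # 50 individuals per population with exact genotype counts at (0.7, 0.3)
    g1 = [[100, 100]] * 24 + [[100, 104]] * 22 + [[104, 104]] * 4   # p(100)=0.7
    g2 = [[100, 100]] * 4 + [[100, 104]] * 22 + [[104, 104]] * 24   # p(100)=0.3
    panel = make_panel(np.array(g1 + g2)[:, None, :], sections=["P1"] * 50 + ["P2"] * 50)
    d, per_locus = jost_dest(panel)
    expected = jost_d_oracle([0.7, 0.3], [0.3, 0.7], 50, 50)
    assert per_locus["loc1"] == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------- AMOVA
def test_amova_null_split_phi_near_zero(hw_panel_factory):
    rng = np.random.default_rng(12)
    panel = hw_panel_factory([[0.4, 0.3, 0.3]] * 5, n=120, seed=3,
                             sections=list(rng.permutation(["A"] * 60 + ["B"] * 60)))
    table = amova(panel, n_permutations=99, seed=1)
    assert abs(table.phi_st) < 0.02
    assert table.p_value > 0.05


def test_amova_components_match_direct_anova_oracle():
    # 3 individuals, 1 locus: groups {i1,i2} and {i3}
    panel = make_panel(
        [[[100, 104]], [[100, 100]], [[104, 104]]], sections=["G1", "G1", "G2"]
    )
    table = amova(panel, n_permutations=0)
    # direct ANOVA on the 6 gene copies coded as indicator of allele 104
    copies = np.array([0, 1, 0, 0, 1, 1], dtype=float)
    groups = np.array([0, 0, 0, 0, 1, 1])
    grand = copies.mean()
    ss_total = np.sum((copies - grand) ** 2)
    ss_within = sum(
        np.sum((copies[groups == g] - copies[groups == g].mean()) ** 2) for g in (0, 1)
    )
    assert table.ss_within == pytest.approx(ss_within)
    assert table.ss_among == pytest.approx(ss_total - ss_within)
    assert table.df_among == 1 and table.df_within == 4 and table.df_total == 5
    # variance components recombine into the total mean squares
    n0 = (6 - (16 + 4) / 6) / 1
    ms_within = ss_within / 4
    ms_among = (ss_total - ss_within) / 1
    assert table.var_within == pytest.approx(ms_within)
    assert table.var_among == pytest.approx((ms_among - ms_within) / n0)


def test_amova_study_scale_df_and_weak_phi():
    panel, truth = simulate_panel(SimConfig(seed=21))  # 324 fish, 5 sections
    table = amova(panel, "section", n_permutations=0)
    assert table.df_among == 4
    assert table.df_within == 2 * 324 - 5
    assert table.df_total == 647
    assert 0.0 <= table.phi_st_floored <= 0.01


# -------------------------------------------------------------------- G-test
def test_g_test_equal_counts_trivial():
    calls = np.array([[[100, 104]]] * 10 + [[[100, 104]]] * 10)
    panel = make_panel(calls, sections=["P1"] * 10 + ["P2"] * 10)
    per_locus, global_res = g_test_differentiation(
        panel, dememorization=100, batches=2, iters_per_batch=100, seed=0
    )
    assert per_locus["loc1"].statistic == 0.0
    assert per_locus["loc1"].p_value == 1.0


def fisher_2x2_g_oracle(table):
    """Complete enumeration of 2x2 tables with fixed margins, hypergeometric
    weights, p = P(G >= G_obs)."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def g_stat(x):
        t = np.array([[x, row1 - x], [col1 - x, n - row1 - col1 + x]], dtype=float)
        e = np.outer(t.sum(1), t.sum(0)) / n
        m = t > 0
        return 2 * np.sum(t[m] * np.log(t[m] / e[m]))

    g_obs = g_stat(a)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if g_stat(x) >= g_obs - 1e-9:
            p += hypergeom.pmf(x, n, row1, col1)
    return p


def test_g_test_mcmc_matches_enumeration_oracle():
    # allele counts 30/10 vs 10/30 -> 2x2 table
    g1 = [[100, 100]] * 10 + [[100, 104]] * 10  # 30 x 100, 10 x 104
    g2 = [[104, 104]] * 10 + [[100, 104]] * 10
    panel = make_panel(np.array(g1 + g2)[:, None, :], sections=["P1"] * 20 + ["P2"] * 20)
    per_locus, _ = g_test_differentiation(
        panel, dememorization=5_000, batches=40, iters_per_batch=2_000, seed=3
    )
    oracle = fisher_2x2_g_oracle([[30, 10], [10, 30]])
    assert per_locus["loc1"].p_value == pytest.approx(oracle, abs=0.01)


def test_g_test_power_on_diverged_stocks():
    """Two stocks at divergence 0.05: the Fisher-combined global test is
    decisive in every replicate."""
    for seed in range(5):
        panel, truth = simulate_panel(
            SimConfig(n_individuals=300, n_loci=14, stock_divergence_fst=0.05,
                      fis=0.0, section_sizes={"A": 150, "B": 150}, seed=seed)
        )
        panel = panel.with_stocks(truth.stocks)
        _, global_res = g_test_differentiation(
            panel, by="stock", dememorization=500, batches=10,
            iters_per_batch=200, seed=seed,
        )
        assert global_res.p_value < 0.001


# ---------------------------------------------------------- pairwise matrix
def test_pairwise_matrix_symmetric_zero_diagonal():
    panel, _ = simulate_panel(SimConfig(n_individuals=90, n_loci=5, seed=2,
                                        section_sizes={"A": 30, "B": 30, "C": 30}))
    mat = pairwise_matrix(panel, "jost_dest")
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 0.0)
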
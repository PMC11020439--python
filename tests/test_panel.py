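"""Genotype data model and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msatpop.panel import (
    GenotypePanel,
    Individual,
    Locus,
    PanelFormatError,
    filter_panel,
    read_panel,
    write_panel,
)
from .conftest import make_panel


# --------------------------------------------------------------- construction
def test_pairs_canonicalized_and_registers_built():
    panel = make_panel([[[104, 100]], [[104, 104]]])
    assert panel.calls[0, 0].tolist() == [100, 104]
    assert panel.loci[0].allele_register == (100, 104)


def test_half_call_rejected():
    with pytest.raises(ValueError, match="half-called"):
        make_panel([[[100, -1]]])


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="unique"):
        GenotypePanel(
            [Locus("x", 4)],
            [Individual("a"), Individual("a")],
            np.array([[[100, 100]], [[100, 100]]]),
        )


# ----------------------------------------------------------------- tabular IO
def test_tabular_minimal_parse(tmp_path):
    path = tmp_path / "mini.csv"
    path.write_text("id,section,season,year,loc1_1,loc1_2\na,S4,dry,2020,100,104\nb,S4,dry,2020,104,104\n")
    panel = read_panel(path, "tabular")
    assert panel.n_individuals == 2
    assert panel.loci[0].allele_register == (100, 104)  # Na = 2
    assert panel.individuals[0].season == "dry"


def test_tabular_missing_and_na(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("id,section,season,year,loc1_1,loc1_2\na,S4,dry,2020,NA,NA\nb,S4,dry,2020,100,100\n")
    panel = read_panel(path, "tabular")
    assert panel.calls[0, 0, 0] == -1


def test_tabular_bad_allele_reports_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("id,section,season,year,loc1_1,loc1_2\na,S4,dry,2020,xx,104\n")
    with pytest.raises(PanelFormatError, match=":2"):
        read_panel(path, "tabular")


# --------------------------------------------------------------- structure IO
def test_structure_two_row_with_missing(tmp_path):
    path = tmp_path / "s.str"
    path.write_text(
        "locA locB\n"
        "f1 1 100 200\n"
        "f1 1 104 204\n"
        "f2 1 -9 200\n"
        "f2 1 -9 200\n"
        "f3 2 100 208\n"
        "f3 2 100 204\n"
    )
    panel = read_panel(path, "structure")
    assert panel.n_individuals == 3
    assert panel.calls[1, 0, 0] == -1          # one missing cell
    assert panel.calls[1, 1].tolist() == [200, 200]
    assert panel.calls[2, 1].tolist() == [204, 208]


def test_structure_half_missing_rejected(tmp_path):
    path = tmp_path / "s.str"
    path.write_text("locA\nf1 1 -9\nf1 1 104\n")
    with pytest.raises(PanelFormatError, match="half-missing"):
        read_panel(path, "structure")


def test_structure_export_shape(tmp_path):
    panel = make_panel(
        np.full((3, 14, 2), 100, dtype=np.int32), sections=["S4", "S4", "S5"]
    )
    path = write_panel(panel, tmp_path / "p.str", "structure")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 + 2 * 3                      # header + 2 rows/individual
    assert lines[0].split() == [f"loc{j + 1}" for j in range(14)]


# ----------------------------------------------------------------- genepop IO
def test_genepop_missing_code_and_sidecar(tmp_path):
    panel = make_panel(
        [[[100, 104]], [[-1, -1]]], sections=["S4", "S5"]
    )
    path = write_panel(panel, tmp_path / "p.gen", "genepop")
    text = path.read_text()
    assert "000000" in text
    back = read_panel(path, "genepop")
    assert back == panel


def test_genepop_too_many_alleles(tmp_path):
    calls = (100 + np.arange(2000).reshape(1000, 1, 2)).astype(np.int32)
    panel = GenotypePanel(
        [Locus("big", 2)], [Individual(f"i{k}") for k in range(1000)], calls
    )
    with pytest.raises(ValueError, match="999"):
        write_panel(panel, tmp_path / "p.gen", "genepop")


def test_empty_panel_write_rejected(tmp_path):
    panel = make_panel(np.zeros((1, 1, 2), dtype=np.int32) + 100).subset(indices=[0])
    empty = GenotypePanel(panel.loci, [], np.zeros((0, 1, 2)))
    for fmt in ("tabular", "genepop", "structure"):
        with pytest.raises(ValueError, match="empty"):
            write_panel(empty, tmp_path / "e", fmt)
    assert not (tmp_path / "e").exists()


# --------------------------------------------------------------- round trips
panel_strategy = st.builds(
    lambda n, L, seed, miss: _random_panel(n, L, seed, miss),
    n=st.integers(2, 8),
    L=st.integers(1, 4),
    seed=st.integers(0, 10_000),
    miss=st.floats(0, 0.3),
)


def _random_panel(n, L, seed, miss):
    rng = np.random.default_rng(seed)
    calls = np.zeros((n, L, 2), dtype=np.int32)
    for j in range(L):
        ladder = 100 + 4 * np.arange(rng.integers(2, 6))
        calls[:, j, :] = rng.choice(ladder, size=(n, 2))
    drop = rng.random((n, L)) < miss
    calls[drop] = -1
    sections = [f"S{rng.integers(4, 7)}" for _ in range(n)]
    seasons = [("rainy", "dry")[rng.integers(2)] for _ in range(n)]
    years = [int(rng.integers(2019, 2022)) for _ in range(n)]
    return make_panel(calls, sections=sections, seasons=seasons, years=years)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(panel=panel_strategy)
def test_roundtrip_identity_tabular_genepop(tmp_path_factory, panel):
    tmp = tmp_path_factory.mktemp("rt")
    for fmt in ("tabular", "genepop"):
        path = write_panel(panel, tmp / f"p.{fmt}", fmt)
        back = read_panel(path, fmt)
        assert back == panel, fmt


@settings(max_examples=25, deadline=None, derandomize=True)
@given(panel=panel_strategy)
def test_roundtrip_structure_preserves_calls(tmp_path_factory, panel):
    tmp = tmp_path_factory.mktemp("rt")
    path = write_panel(panel, tmp / "p.str", "structure")
    back = read_panel(path, "structure")
    assert [loc.name for loc in back.loci] == [loc.name for loc in panel.loci]
    assert np.array_equal(back.calls, panel.calls)


def test_statistics_invariant_to_row_and_allele_order():
    from msatpop.diversity import locus_diversity

    base = make_panel([[[100, 104]], [[104, 108]], [[108, 108]]])
    swapped = make_panel([[[108, 108]], [[108, 104]], [[104, 100]]])
    d1 = locus_diversity(base, "loc1")
    d2 = locus_diversity(swapped, "loc1")
    assert d1.ho == d2.ho and d1.he == d2.he and d1.pic == d2.pic


# --------------------------------------------------------------------- filter
def test_filter_drop_loci_matches_study_screen():
    # 16 loci, drop the two null-ridden ones -> 14 remain
    calls = np.full((4, 16, 2), 100, dtype=np.int32)
    names = [f"Cym{k:02d}" for k in range(1, 17)]
    panel = make_panel(calls, locus_names=names)
    out = filter_panel(panel, drop_loci=["Cym10", "Cym16"])
    assert out.n_loci == 14
    assert "Cym10" not in [l.name for l in out.loci]


def test_filter_maf_zero_is_identity():
    panel = make_panel([[[100, 104]], [[104, 104]]])
    out = filter_panel(panel, min_maf=0.0)
    assert out == panel and not out.ne_masked_alleles


def test_filter_masks_rare_allele_for_ne_only():
    # one allele at frequency 1/100 = 0.01 < 0.02
    geno = [[100, 104]] + [[104, 104]] * 49
    panel = make_panel(geno)
    out = filter_panel(panel, min_maf=0.02)
    assert out.ne_masked_alleles["loc1"] == frozenset({100})
    # diversity still sees both alleles
    from msatpop.diversity import allele_frequencies

    assert len(allele_frequencies(out, "loc1")) == 2


def test_filter_all_loci_dropped_is_error():
    panel = make_panel([[[100, 104]]])
    with pytest.raises(ValueError, match="all loci"):
        filter_panel(panel, drop_loci=["loc1"])
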
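"""Overlap bookkeeping, chord export, and the stringent candidate table."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphos import crosscompare, diffphos
from circaphos.crosscompare import (
    CandidateEntry,
    chord_from_json,
    chord_to_json,
    compare_site_sets,
    export_chord,
    load_candidate_fixture,
    summarize_candidate_annotations,
)
from circaphos.diffphos import DifferentialResult, DifferentialTable, DifferentialCriteria
from circaphos.quantio import PhosphoSiteKey


def _table(up=(), down=(), ns=()):
    def res(site, cls):
        return DifferentialResult(site, 1.0, 1.0, 1.0, 0.5, 0.0, 8.0, cls)

    results = (
        [res(s, "up") for s in up] + [res(s, "down") for s in down] + [res(s, "ns") for s in ns]
    )
    return DifferentialTable(results, DifferentialCriteria())


def _k(name):
    return PhosphoSiteKey(name, (1,))


class TestCompareDatasets:
    def test_small_example(self):
        A = _table(up=[_k("a"), _k("b"), _k("c")])
        B = _table(up=[_k("b"), _k("c"), _k("d")])
        s = crosscompare.compare_datasets(A, B)
        assert (s.up_shared, s.up_A_only, s.up_B_only) == (2, 1, 1)

    def test_identical_tables(self):
        A = _table(up=[_k("a")], down=[_k("z")])
        s = crosscompare.compare_datasets(A, A)
        assert s.up_A_only == s.up_B_only == s.down_A_only == s.down_B_only == 0
        assert s.discordant == 0

    def test_discordant_counted_separately(self):
        A = _table(up=[_k("a"), _k("b")])
        B = _table(down=[_k("b")])
        s = crosscompare.compare_datasets(A, B)
        assert s.discordant == 1
        assert s.up_shared == 0


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    a_up=st.sets(st.integers(0, 30)),
    b_up=st.sets(st.integers(0, 30)),
    a_down=st.sets(st.integers(31, 60)),
    b_down=st.sets(st.integers(31, 60)),
)
def test_marginal_identities(a_up, b_up, a_down, b_down):
    s = compare_site_sets(a_up, b_up, a_down, b_down)
    assert s.up_shared + s.up_A_only == len(a_up)
    assert s.up_shared + s.up_B_only == len(b_up)
    assert s.down_shared + s.down_A_only == len(a_down)
    assert s.down_shared + s.down_B_only == len(b_down)


class TestChordExport:
    def test_zero_summary_empty_matrix(self):
        s = compare_site_sets(set(), set(), set(), set())
        doc = export_chord(s)
        assert all(v == 0 for row in doc["matrix"] for v in row)

    def test_row_sums_equal_marginals(self):
        a_up, b_up = {1, 2, 3}, {2, 3, 4}
        s = compare_site_sets(a_up, b_up, set(), set())
        m = export_chord(s)["matrix"]
        assert sum(m[0]) == len(a_up)
        assert sum(m[1]) == len(b_up)

    def test_row_sums_with_discordant_sites(self):
        a_up, b_down = {1, 2, 3}, {3, 9}
        s = compare_site_sets(a_up, {2}, {8}, b_down)
        m = export_chord(s)["matrix"]
        assert sum(m[0]) == len(a_up)
        assert sum(m[3]) == len(b_down)

    def test_matrix_symmetric(self):
        s = compare_site_sets({1, 2}, {2, 3}, {4}, {4, 5})
        m = export_chord(s)["matrix"]
        for i in range(4):
            for j in range(i):
                assert m[i][j] == m[j][i]

    def test_json_roundtrip(self):
        s = compare_site_sets({1, 2, 3}, {2, 3, 4}, {9}, {9, 10})
        doc = chord_to_json(s)
        assert chord_from_json(doc) == export_chord(s)


class TestCandidateTable:
    def test_categorization_from_set_membership(self):
        up_A = {_k("x"), _k("y")}
        up_B = {_k("y"), _k("z")}
        assert crosscompare.categorize(_k("y"), up_A, up_B) == "both"
        assert crosscompare.categorize(_k("x"), up_A, up_B) == "tau_only"
        assert crosscompare.categorize(_k("z"), up_A, up_B) == "wt_only"
        assert crosscompare.categorize(_k("q"), up_A, up_B) == "neither"

    def test_build_excludes_unregulated_predicted_sites(self):
        A = _table(up=[_k("x")])
        B = _table(up=[_k("x")], ns=[_k("q")])
        predicted = {_k("x"): True, _k("q"): True}
        entries = crosscompare.build_candidate_table(A, B, predicted)
        assert [e.category for e in entries] == ["both"]

    def test_site_count_from_display_string(self):
        e = CandidateEntry("g:s", "ET(p1)KT(p2,3)LAELMS(p3)INMGA", "both")
        assert e.n_sites == 3
        assert CandidateEntry("g:s", "S(p)LGLLPGPTK", "both").n_sites == 1


class TestAnnotationFixture:
    def test_fixture_shape(self):
        entries = load_candidate_fixture()
        assert len(entries) == 19
        assert {e.category for e in entries} == {"both", "tau_only", "wt_only", "neither"}

    def test_asparaginase_entry_upregulated_in_both(self):
        entries = load_candidate_fixture()
        (e,) = [x for x in entries if x.gene_id == "Ot13g02360"]
        assert e.peptide_display == "S(p)LGLLPGPTK"
        assert e.category == "both"

    def test_stringent_both_counts(self):
        """Sites upregulated in both overexpression lines and predicted as
        CK1 targets: 12 sites on 10 proteins."""
        entries = [e for e in load_candidate_fixture() if e.category == "both"]
        summary = summarize_candidate_annotations(entries)
        assert summary.n_predicted_sites_by_category["both"] == 12
        assert summary.n_proteins_by_category["both"] == 10

    def test_single_line_predicted_sites(self):
        entries = load_candidate_fixture()
        summary = summarize_candidate_annotations(entries)
        assert (
            summary.n_predicted_sites_by_category["tau_only"]
            + summary.n_predicted_sites_by_category["wt_only"]
            == 3
        )

    def test_clock_annotation_counts(self):
        """Of the candidates with a resolved human homolog, two thirds alter
        the human cellular clock when knocked down: 10 of 15."""
        summary = summarize_candidate_annotations(load_candidate_fixture())
        assert summary.n_with_homolog == 15
        assert summary.n_alter_clock == 10

    def test_all_unknown_annotations_zero_counts(self):
        entries = [
            CandidateEntry("g:1", "S(p)AAK", "both", homolog=None),
            CandidateEntry("g:2", "T(p)AAK", "both", homolog=None),
        ]
        summary = summarize_candidate_annotations(entries)
        assert summary.n_with_homolog == 0
        assert summary.n_alter_clock == 0


def test_candidates_tsv_export(tmp_path):
    import pandas as pd

    entries = load_candidate_fixture()
    out = tmp_path / "candidates.tsv"
    crosscompare.candidates_to_tsv(entries, out)
    df = pd.read_csv(out, sep="\t")
    assert len(df) == 19
    assert "category" in df.columns
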
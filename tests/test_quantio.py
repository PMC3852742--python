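"""Peptide quant table parsing and peptide-to-site collation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaphos import quantio, synthdata
from conftest import make_measurement

from circaphos.quantio import PhosphoSiteKey, parse_mods


class TestModsParsing:
    def test_single_site(self):
        (site,) = parse_mods("S3", "AKS")
        assert site.positions == (3,)
        assert not site.ambiguous

    def test_ambiguity_group(self):
        (site,) = parse_mods("T5(amb:T7)", "AKSRTATY")
        assert site.positions == (5, 7)
        assert site.ambiguous

    def test_multiple_groups(self):
        sites = parse_mods("S3;T5(amb:T7)", "AKSRTATY")
        assert len(sites) == 2

    def test_position_on_wrong_residue_rejected(self):
        with pytest.raises(ValueError, match="not 'S'"):
            parse_mods("S3", "ASK")

    def test_position_outside_peptide_rejected(self):
        with pytest.raises(ValueError, match="outside peptide"):
            parse_mods("S9", "ASK")

    def test_non_phospho_residue_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_mods("K2", "AKS")


class TestReadQuantTable:
    def test_well_formed_file(self, quant_csv):
        measurements = quantio.read_quant_table(quant_csv)
        assert len(measurements) == 3
        assert all(m.peptide == "SLGLLPGPTK" for m in measurements)

    def test_missing_column_named(self, quant_csv, tmp_path):
        df = pd.read_csv(quant_csv).drop(columns=["abundance"])
        p = tmp_path / "broken.csv"
        df.to_csv(p, index=False)
        with pytest.raises(quantio.SchemaError, match="abundance"):
            quantio.read_quant_table(p)

    def test_negative_abundance_reports_row(self, quant_csv, tmp_path):
        df = pd.read_csv(quant_csv)
        df.loc[1, "abundance"] = -5.0
        p = tmp_path / "neg.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 2"):
            quantio.read_quant_table(p)


class TestSiteKey:
    def test_equality_ignores_display_fields(self):
        a = PhosphoSiteKey("P1", (3,), ("S",), False)
        b = PhosphoSiteKey("P1", (3,))
        assert a == b and hash(a) == hash(b)

    def test_positions_must_be_sorted_unique(self):
        with pytest.raises(ValueError):
            PhosphoSiteKey("P1", (5, 3))

    def test_label(self):
        key = PhosphoSiteKey("P1", (12, 14), ("T", "T"))
        assert key.label == "P1:T12/T14"


class TestCollation:
    def test_charge_states_and_missed_cuts_summed(self, tiny_proteome):
        """One site seen at charge 2 (100), charge 3 (200), and with a missed
        cleavage (50) in one replicate collapses to a single 350 cell."""
        measurements = [
            make_measurement(charge=2, abundance=100.0),
            make_measurement(charge=3, abundance=200.0),
            make_measurement(charge=2, missed_cleavages=1, abundance=50.0),
        ]
        sqt = quantio.collate_sites(measurements, tiny_proteome)
        assert sqt.n_sites == 1
        key = sqt.sites[0]
        assert key == PhosphoSiteKey("P1", (3,))
        assert sqt.data.loc[key, ("parent", 1)] == pytest.approx(350.0)
        assert sqt.n_source_peptides[key] == 3

    def test_two_distinct_sites_two_rows(self, tiny_proteome):
        measurements = [
            make_measurement(),
            make_measurement(peptide="PGPTKAA", mods="T4", abundance=10.0),
        ]
        sqt = quantio.collate_sites(measurements, tiny_proteome)
        assert sqt.n_sites == 2

    def test_empty_input(self, tiny_proteome):
        sqt = quantio.collate_sites([], tiny_proteome)
        assert sqt.n_sites == 0
        assert sqt.total_abundance() == 0.0

    def test_unmappable_peptide_goes_to_skip_report(self, tiny_proteome):
        m = make_measurement(peptide="YYYYWWWWYY", mods="Y1")
        sqt = quantio.collate_sites([m], tiny_proteome)
        assert sqt.n_sites == 0
        assert len(sqt.skipped) == 1
        assert "no exact proteome match" in sqt.skipped[0].reason

    def test_idempotent_on_site_level_data(self, tiny_proteome):
        """With one variant per site, collation is the identity on abundances."""
        measurements = [
            make_measurement(group=g, replicate=r, abundance=100.0 * r + (g == "ox"))
            for g in ("parent", "ox")
            for r in (1, 2, 3)
        ]
        sqt = quantio.collate_sites(measurements, tiny_proteome)
        for m in measurements:
            assert sqt.data.loc[PhosphoSiteKey("P1", (3,)), (m.group, m.replicate)] == m.abundance


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_collation_conserves_total_abundance(seed):
    """Summed site table total equals the peptide input total on generated
    data, across redundancy, missingness and seeds."""
    cfg = synthdata.PhosphoSimConfig(
        n_proteins=4, n_sites=12, protein_length=300,
        redundancy_max=4, missing_rate=0.15, seed=seed,
    )
    table, truth = synthdata.generate_phospho_dataset(cfg)
    measurements = quantio.measurements_from_frame(table)
    sqt = quantio.collate_sites(measurements, truth.proteome)
    assert sqt.total_abundance() == pytest.approx(table["abundance"].sum(), rel=1e-12)
    assert not sqt.skipped


def test_site_count_matches_generator_truth():
    cfg = synthdata.PhosphoSimConfig(n_proteins=10, n_sites=50, seed=5)
    table, truth = synthdata.generate_phospho_dataset(cfg)
    sqt = quantio.collate_sites(quantio.measurements_from_frame(table), truth.proteome)
    assert sqt.n_sites == 50
    assert set(sqt.sites) == set(truth.site_class)


def test_curated_candidate_peptide_maps_onto_packaged_context_window():
    """The asparaginase-like peptide SLGLLPGPTK locates its phospho-serine in
    the packaged (synthetic-flank) Ot13g02360 context window."""
    from importlib import resources

    source = resources.files("circaphos.data").joinpath("ot_context_synthetic.fasta")
    with resources.as_file(source) as p:
        proteome = quantio.read_fasta(p)
    m = make_measurement(protein="Ot13g02360")
    sqt = quantio.collate_sites([m], proteome)
    (key,) = sqt.sites
    assert key.protein_id == "Ot13g02360"
    assert key.positions == (11,)
    assert key.residues == ("S",)


def test_tsv_export_roundtrip_columns(tmp_path, tiny_proteome):
    sqt = quantio.collate_sites([make_measurement()], tiny_proteome)
    out = tmp_path / "sites.tsv"
    sqt.to_tsv(out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["protein_id", "positions", "group", "replicate", "abundance"]
    assert df.loc[0, "positions"] == "S3"
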
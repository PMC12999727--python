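"""Evidence joining, summary-table aggregation, environment breakdowns."""

import pytest

from rubiscan.rbcl_phylo import FormLabel
from rubiscan.reporting import (
    GRAND,
    StrainMetadata,
    SummaryTable,
    expand_order_counts,
    join_evidence,
    load_survey_order_counts,
    summarize,
    summarize_environments,
    summary_from_order_counts,
)
from rubiscan.trait_engine import TraitProfile


def _profile(genome_id, forms=(), h2=False, photosystem=False):
    return TraitProfile(
        genome_id=genome_id,
        h2_uptake=h2,
        sulfur_oxidation="none",
        oxygen_aerobic_lowaff=False,
        oxygen_microaerophilic_highaff=False,
        nitrate_reduction=False,
        sulfur_reduction=False,
        photosystem_ii=photosystem,
        forms_present=frozenset(forms),
    )


def _meta(genome_id, phylum="Pseudomonadota", order="Rhodobacterales", genus="Cereibacter",
          evidence="untested", environment="marine"):
    return StrainMetadata(genome_id, phylum, order, genus, evidence, environment)


class TestJoin:
    def test_full_metadata_yields_one_record_per_profile(self):
        profiles = [_profile(f"g{i}") for i in range(3)]
        records = join_evidence(profiles, [_meta(f"g{i}") for i in range(3)])
        assert len(records) == 3
        assert all(r.metadata.environment == "marine" for r in records)

    def test_missing_metadata_defaults_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            records = join_evidence([_profile("orphan")], [])
        assert records[0].metadata.evidence == "untested"
        assert records[0].metadata.environment == "unknown"
        assert "no metadata" in caplog.text

    def test_genus_evidence_propagates_to_all_members(self):
        profiles = [_profile("g1"), _profile("g2")]
        metadata = [
            _meta("g1", genus="Thermus", evidence="demonstrated"),
            _meta("g2", genus="Thermus", evidence="untested"),
        ]
        records = join_evidence(profiles, metadata)
        assert all(r.genus_evidence for r in records)

    def test_duplicate_metadata_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            join_evidence([_profile("g1")], [_meta("g1"), _meta("g1")])


class TestSummarize:
    def test_single_record_counts_once_everywhere(self):
        records = join_evidence([_profile("g1", forms={FormLabel.IA}, h2=True)], [_meta("g1")])
        table = summarize(records, scope="all")
        assert table.grand_total() == 1
        assert table.grand_total("IA") == 1
        assert table.grand_total("h2_oxidation") == 1
        assert table.order_row("Pseudomonadota", "Rhodobacterales")["strains"] == 1

    def test_empty_records_give_zero_table(self):
        table = summarize([], scope="all")
        assert table.grand_total() == 0

    def test_record_order_invariance(self):
        profiles = [_profile(f"g{i}", forms={FormLabel.IC}) for i in range(6)]
        metadata = [_meta(f"g{i}", order=("Thermales" if i % 2 else "Rhodobacterales")) for i in range(6)]
        records = join_evidence(profiles, metadata)
        forward = summarize(records, scope="all")
        assert forward == summarize(records[::-1], scope="all")

    def test_untested_scope_drops_evidence_positive_genera(self):
        profiles = [_profile("g1"), _profile("g2")]
        metadata = [
            _meta("g1", genus="Thermus", evidence="demonstrated"),
            _meta("g2", genus="Jiella"),
        ]
        records = join_evidence(profiles, metadata)
        assert summarize(records, scope="untested-genera").grand_total() == 1
        assert summarize(records, scope="all").grand_total() == 2

    def test_tsv_round_trip_is_cell_exact(self, tmp_path):
        records = join_evidence(
            [_profile("g1", forms={FormLabel.IA}), _profile("g2", photosystem=True)],
            [_meta("g1"), _meta("g2", phylum="Actinomycetota", order="Mycobacteriales")],
        )
        table = summarize(records, scope="all")
        path = tmp_path / "summary.tsv"
        table.to_tsv(path)
        assert SummaryTable.from_tsv(path) == table

    def test_zeros_render_as_blank_cells(self, tmp_path):
        records = join_evidence([_profile("g1")], [_meta("g1")])
        path = tmp_path / "summary.tsv"
        summarize(records, scope="all").to_tsv(path)
        body = path.read_text().splitlines()[1]
        assert "\t0" not in body  # zero counts are blanks, not zeros

    def test_conservation_check_catches_corruption(self):
        table = summarize(
            join_evidence([_profile("g1")], [_meta("g1")]), scope="all"
        )
        corrupt = table.frame.copy()
        corrupt.loc[corrupt["phylum"] == GRAND, "strains"] = 99
        with pytest.raises(ValueError, match="conservation"):
            SummaryTable(corrupt)


class TestSurveyFixture:
    def test_grand_totals_match_published_matrix(self):
        table = summary_from_order_counts(load_survey_order_counts())
        assert table.grand_total() == 144
        assert table.grand_total("IC") == 58

    def test_expansion_reproduces_order_rows(self):
        rows = load_survey_order_counts()
        table = summary_from_order_counts(rows)
        for row in rows:
            got = table.order_row(row["phylum"], row["order"])
            for column, value in got.items():
                assert value == int(row[column])


class TestEnvironments:
    def test_empty_stratum_is_all_zero(self):
        counts = summarize_environments([], stratify_by=FormLabel.IE)
        assert counts["total"] == 0
        assert all(counts[e] == 0 for e in ("marine", "terrestrial", "food"))

    def test_single_category_concentrates_total(self):
        records = join_evidence(
            [_profile(f"g{i}", forms={FormLabel.II}) for i in range(5)],
            [_meta(f"g{i}", environment="engineered") for i in range(5)],
        )
        counts = summarize_environments(records, stratify_by=FormLabel.II)
        assert counts["engineered"] == counts["total"] == 5

    def test_rhizosphere_folds_into_terrestrial_tally(self):
        records = join_evidence(
            [_profile("g1"), _profile("g2")],
            [_meta("g1", environment="terrestrial"), _meta("g2", environment="rhizosphere_plant")],
        )
        counts = summarize_environments(records)
        assert counts["terrestrial_incl_rhizosphere"] == 2
        assert counts["plant_associated"] == 1
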
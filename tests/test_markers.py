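"""Marker catalog loading and similarity-based marker assignment."""

import pytest

from rubiscan.markers import (
    GenomeRecord,
    MarkerCatalog,
    MarkerDef,
    ProteinRecord,
    SeedSequence,
    load_catalog,
    read_annotation_table,
    search_markers,
    write_hits_tsv,
)
from rubiscan.synthetic_data import mutate_sequence, shuffle_sequence

from oracles import nw_align


def _seed_of(catalog, marker_id, which=0):
    return sorted(catalog[marker_id].seeds, key=lambda s: s.label)[which].sequence


def _genome(*sequences):
    proteins = tuple(
        ProteinRecord(protein_id=f"p{i}", sequence=seq, locus_index=i) for i, seq in enumerate(sequences)
    )
    return GenomeRecord(genome_id="G1", strain_label="G1", proteins=proteins)


class TestCatalog:
    def test_default_catalog_contains_cbb_module_markers(self, catalog):
        for ko in ("K00855", "K01601", "K00927", "K05298", "K00150", "K00134"):
            assert ko in catalog
        assert len(catalog) >= 40

    def test_duplicate_marker_id_rejected(self):
        seed = SeedSequence("s1", "MKTAYIAKQR")
        marker = MarkerDef("soxZ", "sulfur_ox", (seed,))
        with pytest.raises(ValueError, match="duplicate"):
            MarkerCatalog([marker, marker], require_mandatory=False)

    def test_empty_catalog_file_rejected(self, tmp_path):
        empty = tmp_path / "empty.yaml"
        empty.write_text("")
        with pytest.raises(ValueError):
            load_catalog(empty)

    def test_missing_mandatory_marker_named_in_error(self, tmp_path):
        path = tmp_path / "partial.yaml"
        path.write_text(
            "markers:\n"
            "  - marker_id: K00855\n"
            "    category: cbb\n"
            "    seeds:\n"
            "      - {label: s1, sequence: MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ}\n"
        )
        with pytest.raises(ValueError, match="K01601"):
            load_catalog(path)

    def test_thresholds_validated(self):
        seed = SeedSequence("s1", "MKTAYIAKQR")
        with pytest.raises(ValueError, match="min_identity"):
            MarkerDef("soxZ", "sulfur_ox", (seed,), min_identity=0.0)


class TestSearch:
    @pytest.mark.parametrize("marker_id", ["soxZ", "pufL", "K00855"])
    def test_seed_protein_hits_own_marker_at_identity_one(self, catalog, marker_id):
        genome = _genome(_seed_of(catalog, marker_id))
        hits = search_markers(genome, catalog)
        assert [h.marker_id for h in hits] == [marker_id]
        assert hits[0].identity == pytest.approx(1.0)
        assert hits[0].coverage == pytest.approx(1.0)

    def test_shuffled_sequences_produce_no_hits(self, catalog, rng):
        decoys = [shuffle_sequence(_seed_of(catalog, m), rng) for m in ("soxA", "narG", "pufM")]
        assert search_markers(_genome(*decoys), catalog) == []

    def test_distant_mutant_recovered_and_identity_matches_oracle(self, catalog, rng):
        """A gene at ~60% identity to its seed is still assigned (floor 0.40),
        and the reported identity agrees with an independent DP alignment."""
        seed = _seed_of(catalog, "soxA")
        mutant = mutate_sequence(seed, 0.60, rng)
        hits = search_markers(_genome(mutant), catalog)
        assert [h.marker_id for h in hits] == ["soxA"]
        _, oracle_identity = nw_align(mutant, seed)
        assert hits[0].identity == pytest.approx(oracle_identity, abs=1e-9)

    def test_search_is_permutation_invariant(self, catalog, rng):
        seqs = [
            mutate_sequence(_seed_of(catalog, m), 0.85, rng, verify=False)
            for m in ("K00855", "soxZ", "narH", "pufL")
        ]
        forward = search_markers(_genome(*seqs), catalog)
        reversed_hits = search_markers(_genome(*seqs[::-1]), catalog)
        key = lambda h: (h.marker_id, round(h.identity, 9), round(h.score, 3))
        assert sorted(map(key, forward)) == sorted(map(key, reversed_hits))

    def test_protein_with_illegal_characters_skipped(self, catalog, caplog):
        good = _seed_of(catalog, "soxZ")
        genome = _genome("MKTJ" + good[4:], good)  # J is not in the alphabet
        with caplog.at_level("WARNING"):
            hits = search_markers(genome, catalog)
        assert [h.protein_id for h in hits] == ["p1"]
        assert "amino-acid alphabet" in caplog.text

    def test_x_residues_never_count_as_matches(self, catalog):
        seed = _seed_of(catalog, "soxZ")
        masked = "X" * 10 + seed[10:]
        hits = search_markers(_genome(masked), catalog, prescreen=False)
        assert hits and hits[0].identity == pytest.approx((len(seed) - 10) / len(seed))

    def test_empty_catalog_rejected(self, catalog):
        genome = _genome(_seed_of(catalog, "soxZ"))
        class Empty:
            def __len__(self):
                return 0
        with pytest.raises(ValueError):
            search_markers(genome, Empty())


class TestAnnotationTable:
    HEADER = "genome_id\tprotein_id\tmarker_id\n"

    def test_well_formed_rows_become_hits(self, catalog, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(self.HEADER + "G1\tp1\tK00855\nG1\tp2\tK01601\nG2\tp1\tsoxB\n")
        hits = read_annotation_table(path, catalog)
        assert len(hits) == 3
        assert all(h.identity == 1.0 and h.coverage == 1.0 for h in hits)
        assert all(h.provenance == "imported" for h in hits)

    def test_unknown_marker_dropped_with_warning(self, catalog, tmp_path, caplog):
        path = tmp_path / "ann.tsv"
        path.write_text(self.HEADER + "G1\tp1\tK99999\nG1\tp2\tK00855\n")
        with caplog.at_level("WARNING"):
            hits = read_annotation_table(path, catalog)
        assert [h.marker_id for h in hits] == ["K00855"]
        assert "K99999" in caplog.text

    def test_unknown_marker_raises_in_strict_mode(self, catalog, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(self.HEADER + "G1\tp1\tK99999\n")
        with pytest.raises(ValueError, match="K99999"):
            read_annotation_table(path, catalog, on_unknown_marker="error")

    def test_empty_table_with_header_is_empty_list(self, catalog, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(self.HEADER)
        assert read_annotation_table(path, catalog) == []

    def test_missing_columns_rejected(self, catalog, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("genome_id\tprotein_id\nG1\tp1\n")
        with pytest.raises(ValueError, match="columns"):
            read_annotation_table(path, catalog)


def test_hits_tsv_written_with_header(catalog, tmp_path):
    genome = _genome(_seed_of(catalog, "soxZ"))
    hits = search_markers(genome, catalog)
    out = tmp_path / "hits.tsv"
    write_hits_tsv(hits, out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["genome_id", "protein_id", "marker_id"]
    assert len(lines) == 1 + len(hits)


def test_genome_record_requires_increasing_loci():
    p = ProteinRecord("p0", "MKT", 2)
    q = ProteinRecord("p1", "MKT", 1)
    with pytest.raises(ValueError, match="strictly increasing"):
        GenomeRecord(genome_id="G", proteins=(p, q))
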
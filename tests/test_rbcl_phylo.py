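"""Clustering, alignment trimming, form assignment, rbcS, and NJ trees."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from rubiscan._align import pairwise_identity
from rubiscan.markers import GenomeRecord, MarkerHit, ProteinRecord
from rubiscan.rbcl_phylo import (
    FormLabel,
    StrainEntry,
    assign_form,
    build_nj_tree,
    cluster_sequences,
    detect_rbcs,
    nj_from_distances,
    select_representatives,
    trim_alignment,
)
from rubiscan.synthetic_data import mutate_sequence

from oracles import greedy_cluster


def _entry(panel, ref_id):
    return next(e for e in panel if e.ref_id == ref_id)


class TestClustering:
    def test_identical_pair_forms_one_cluster(self):
        result = cluster_sequences([("b", "MKTAYIAKQRQISFVKSHFSRQ"), ("a", "MKTAYIAKQRQISFVKSHFSRQ")])
        assert len(result.clusters) == 1
        rep, members = result.clusters[0]
        assert rep == "a"  # equal length: lexicographically first id founds the cluster
        assert set(members) == {"a", "b"}

    def test_pair_below_threshold_splits(self, panel, rng):
        seq = _entry(panel, "IA.1").sequence
        mutant = mutate_sequence(seq, 0.75, rng)
        realized = pairwise_identity(seq, mutant)
        assert 0.72 <= realized <= 0.78  # constructed to straddle nothing: clearly below 0.80
        result = cluster_sequences([("orig", seq), ("mut", mutant)], threshold=0.80)
        assert len(result.clusters) == 2

    def test_membership_matches_bruteforce_oracle(self, catalog, rng):
        """20 synthetic sequences: greedy membership equals the reference
        implementation that tests each sequence against representatives."""
        bases = [sorted(catalog[m].seeds, key=lambda s: s.label)[0].sequence[:150] for m in ("soxA", "narG", "coxA", "sqr")]
        seqs = []
        for i in range(20):
            base = bases[i % len(bases)]
            identity = 0.65 + 0.3 * rng.random()
            seqs.append((f"s{i:02d}", mutate_sequence(base, identity, rng, verify=False)))
        result = cluster_sequences(seqs, threshold=0.80)
        got = {member: rep for rep, members in result.clusters for member in members}
        expected = greedy_cluster(seqs, 0.80, pairwise_identity)
        assert got == expected

    def test_threshold_one_gives_singletons(self):
        seqs = [("a", "MKTAYIAKQRQISFVKSHF"), ("b", "MKTAYIAKQRQISFVKSHY"), ("c", "AKTAYIAKQRQISFVKSHF")]
        result = cluster_sequences(seqs, threshold=1.0)
        assert len(result.clusters) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_sequences([])


class TestTrimming:
    def test_gap_fraction_rule_on_columns(self):
        # 10 rows; column 0: 1 gap (keep, 0.9>=0.8); column 1: 3 gaps (drop, 0.7<0.8)
        rows = []
        for i in range(10):
            c0 = "-" if i == 0 else "A"
            c1 = "-" if i < 3 else "C"
            rows.append((f"r{i}", c0 + c1 + "D"))
        trimmed = trim_alignment(rows, gap_threshold=0.8)
        assert trimmed.kept_columns == (0, 2)
        assert trimmed.rows[0] == "-D"

    def test_gapless_alignment_is_identity_operation(self):
        rows = [("a", "MKTA"), ("b", "MKTC")]
        trimmed = trim_alignment(rows)
        assert trimmed.kept_columns == (0, 1, 2, 3)
        assert trimmed.rows == ("MKTA", "MKTC")

    def test_all_columns_removed_is_an_error(self):
        rows = [("a", "A-"), ("b", "-C"), ("c", "--"), ("d", "--")]
        with pytest.raises(ValueError, match="gap_threshold"):
            trim_alignment(rows, gap_threshold=0.9)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            trim_alignment([("a", "MKT"), ("b", "MK")])


class TestFormAssignment:
    def test_panel_entry_assigned_its_own_form(self, panel):
        entry = _entry(panel, "IE.1")
        assignment = assign_form(entry.sequence, panel)
        assert assignment.form == FormLabel.IE
        assert assignment.identity_to_nearest == pytest.approx(1.0)
        assert assignment.margin > 0

    def test_mutant_at_85pct_recovers_its_form(self, panel, rng):
        entry = _entry(panel, "IE.1")
        mutant = mutate_sequence(entry.sequence, 0.85, rng)
        assignment = assign_form(mutant, panel)
        assert assignment.form == FormLabel.IE
        # exhaustive nearest-neighbour check over the whole panel
        best = max(panel, key=lambda e: pairwise_identity(mutant, e.sequence))
        assert assignment.nearest_ref_id == best.ref_id

    def test_balanced_chimera_is_unassigned(self, panel):
        """A chimera taking IA/IB residues alternately at disagreeing sites
        sits equidistant from both forms: margin < floor -> UNASSIGNED."""
        a = _entry(panel, "IA.1").sequence
        b = _entry(panel, "IB.1").sequence
        take_a = True
        chimera = []
        for x, y in zip(a, b):
            if x == y:
                chimera.append(x)
            else:
                chimera.append(x if take_a else y)
                take_a = not take_a
        assignment = assign_form("".join(chimera), panel)
        assert assignment.form == FormLabel.UNASSIGNED
        assert assignment.margin < 0.02

    def test_short_sequence_unassigned_with_warning(self, panel, caplog):
        with caplog.at_level("WARNING"):
            assignment = assign_form("MKTAYIAKQR" * 5, panel)  # 50 residues
        assert assignment.form == FormLabel.UNASSIGNED
        assert "shorter" in caplog.text

    def test_identity_is_symmetric(self, panel, rng):
        seq = _entry(panel, "II.1").sequence
        for target in (0.9, 0.7, 0.6):
            mutant = mutate_sequence(seq, target, rng, verify=False)
            assert pairwise_identity(seq, mutant) == pytest.approx(
                pairwise_identity(mutant, seq), abs=1e-12
            )


class TestRbcS:
    def _genome_with_loci(self, n=30):
        proteins = tuple(ProteinRecord(f"p{i}", "MKTAYIAKQR", i) for i in range(n))
        return GenomeRecord(genome_id="G1", proteins=proteins)

    def _hit(self, protein_id, marker_id):
        return MarkerHit("G1", protein_id, marker_id, "s1", 1.0, 1.0, 50.0)

    def test_adjacent_rbcs_is_colocalized(self):
        genome = self._genome_with_loci()
        present, coloc = detect_rbcs(genome, self._hit("p10", "K01601"), [self._hit("p11", "rbcS")])
        assert (present, coloc) == (True, True)

    def test_absent_rbcs(self):
        genome = self._genome_with_loci()
        present, coloc = detect_rbcs(genome, self._hit("p10", "K01601"), [])
        assert (present, coloc) == (False, False)

    def test_distant_rbcs_present_but_not_colocalized(self):
        genome = self._genome_with_loci()
        present, coloc = detect_rbcs(genome, self._hit("p5", "K01601"), [self._hit("p25", "rbcS")], window=5)
        assert (present, coloc) == (True, False)


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        # d(a,b)=4, d(a,c)=6, d(b,c)=8 -> a=1, b=3, c=5
        tree = nj_from_distances(["a", "b", "c"], np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float))
        parsed = TreeNode.read(io.StringIO(tree.newick))
        lengths = {tip.name: tip.length for tip in parsed.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 3.0, "c": 5.0})

    def test_recovers_additive_five_taxon_topology(self):
        # classic additive matrix: cherries (a,b) and (d,e)
        matrix = np.array(
            [
                [0, 5, 9, 9, 8],
                [5, 0, 10, 10, 9],
                [9, 10, 0, 8, 7],
                [9, 10, 8, 0, 3],
                [8, 9, 7, 3, 0],
            ],
            dtype=float,
        )
        tree = nj_from_distances(list("abcde"), matrix)
        parsed = TreeNode.read(io.StringIO(tree.newick))
        expected = TreeNode.read(io.StringIO("((a,b),c,(d,e));"))
        assert parsed.compare_rfd(expected) == 0.0

    def test_identical_sequences_form_zero_length_cherry(self, panel):
        x = _entry(panel, "IA.1").sequence
        y = _entry(panel, "II.1").sequence
        z = _entry(panel, "III.1").sequence
        tree = build_nj_tree([("dup1", x), ("dup2", x), ("other1", y), ("other2", z)])
        parsed = TreeNode.read(io.StringIO(tree.newick))
        assert parsed.find("dup1").length == pytest.approx(0.0)
        assert parsed.find("dup2").length == pytest.approx(0.0)

    def test_leaf_set_matches_input(self, panel):
        seqs = [(f"q{i}", _entry(panel, ref).sequence) for i, ref in enumerate(["IA.1", "IB.1", "II.1"])]
        tree = build_nj_tree(seqs)
        assert set(tree.leaves) == {"q0", "q1", "q2"}

    def test_too_few_sequences_rejected(self, panel):
        with pytest.raises(ValueError, match="at least 3"):
            build_nj_tree([("a", "MKTA" * 30), ("b", "MKTA" * 30)])


class TestRepresentativeSelection:
    def test_evidence_positive_genus_contributes_one(self):
        entries = [
            StrainEntry("g1", "JCM 100", "Thermus", False),
            StrainEntry("g2", "JCM 050", "Thermus", True),
            StrainEntry("g3", "JCM 200", "Thermus", False),
        ]
        assert select_representatives(entries) == ["g2"]

    def test_evidence_lacking_genus_contributes_all(self):
        entries = [StrainEntry(f"g{i}", f"JCM {i}", "Jiella", False) for i in range(4)]
        assert sorted(select_representatives(entries)) == ["g0", "g1", "g2", "g3"]

    def test_empty_input_empty_output(self):
        assert select_representatives([]) == []

    def test_missing_genus_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            selected = select_representatives([StrainEntry("g1", "JCM 1", "", False)])
        assert selected == []
        assert "no genus" in caplog.text
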
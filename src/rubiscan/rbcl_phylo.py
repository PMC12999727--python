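"""RubisCO large-subunit (RbcL) form classification and desk-scale phylogenetics.

RbcL sequences fall into deep clades ("forms") with distinct physiology:
form I (subgroups IA-IE, the Thermus clade, and the small-subunit-lacking
variants I', I'', I-alpha, I-Anaero), form II, form III, and the
RubisCO-like form IV.  This module assigns forms by nearest-reference
identity against a labelled panel, clusters sequences at an identity
threshold to pick representatives, trims alignments by gap fraction,
checks rbcS co-occurrence/colocalization, and builds a neighbor-joining
tree from identity distances as a desk-scale stand-in for full
maximum-likelihood inference (alignments can be exported for external ML
tools via :func:`write_alignment_fasta`).

The bundled reference panel is a synthetic stand-in whose entries
emulate the divergence structure of the real form clades (two entries
per form; see ``data/synthetic_rbcl_panel.fasta``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._align import aligned_identity_rows, pairwise_identity
from .markers import GenomeRecord, MarkerHit

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_THRESHOLD = 0.80
DEFAULT_GAP_THRESHOLD = 0.80
DEFAULT_IDENTITY_FLOOR = 0.45
DEFAULT_MARGIN_FLOOR = 0.02
DEFAULT_COLOCALIZATION_WINDOW = 5
MIN_ASSIGNABLE_LENGTH = 100


class FormLabel(str, Enum):
    """RubisCO form clades; UNASSIGNED marks calls below the floors."""

    IA = "IA"
    IB = "IB"
    IC = "IC"
    ID = "ID"
    IE = "IE"
    I_THERMUS = "I_THERMUS"
    I_PRIME = "I_PRIME"
    I_DOUBLE_PRIME = "I_DOUBLE_PRIME"
    I_ALPHA = "I_ALPHA"
    I_ANAERO = "I_ANAERO"
    II = "II"
    III = "III"
    IV = "IV"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class PanelEntry:
    ref_id: str
    form: FormLabel
    sequence: str
    provenance: str = ""


class ReferencePanel:
    """Labelled RbcL reference sequences, >=1 entry per assignable form."""

    def __init__(self, entries: Iterable[PanelEntry], require_all_forms: bool = True):
        self.entries: tuple[PanelEntry, ...] = tuple(entries)
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference panel has duplicate ref_ids")
        covered = {e.form for e in self.entries}
        if FormLabel.UNASSIGNED in covered:
            raise ValueError("reference panel may not contain UNASSIGNED entries")
        if require_all_forms:
            missing = [f.value for f in FormLabel if f != FormLabel.UNASSIGNED and f not in covered]
            if missing:
                raise ValueError(f"reference panel lacks entries for forms: {', '.join(missing)}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ClusterSet:
    """Result of greedy identity clustering."""

    threshold: float
    clusters: tuple[tuple[str, tuple[str, ...]], ...]  # (representative_id, member_ids)


@dataclass(frozen=True)
class RbcLAssignment:
    """Per-RbcL-copy form call with nearest reference and rbcS context."""

    genome_id: str
    protein_id: str
    form: FormLabel
    nearest_ref_id: str
    identity_to_nearest: float
    margin: float
    rbcs_present: bool = False
    rbcs_colocalized: bool = False


@dataclass(frozen=True)
class TrimmedAlignment:
    sequence_ids: tuple[str, ...]
    kept_columns: tuple[int, ...]  # 0-based indices into the untrimmed alignment
    rows: tuple[str, ...]


@dataclass(frozen=True)
class DistanceTree:
    """Unrooted NJ tree over sequence ids, serialised as Newick."""

    leaves: tuple[str, ...]
    newick: str


def load_panel(path: str | Path, require_all_forms: bool = True) -> ReferencePanel:
    """Read a reference panel from FASTA.

    Headers are ``>ref_id form=<LABEL> <free-text provenance>``.
    """
    from Bio import SeqIO

    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = record.description.split(None, 2)
        if len(fields) < 2 or not fields[1].startswith("form="):
            raise ValueError(f"panel header {record.description!r} lacks a form= tag")
        form = FormLabel(fields[1][len("form=") :])
        provenance = fields[2] if len(fields) > 2 else ""
        entries.append(PanelEntry(record.id, form, str(record.seq).upper(), provenance))
    return ReferencePanel(entries, require_all_forms=require_all_forms)


def default_panel() -> ReferencePanel:
    """The bundled synthetic reference panel (two entries per form)."""
    ref = resources.files("rubiscan.data") / "synthetic_rbcl_panel.fasta"
    with resources.as_file(ref) as path:
        return load_panel(path)


def cluster_sequences(
    seqs: Sequence[tuple[str, str]],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> ClusterSet:
    """Greedy incremental identity clustering, longest sequence first.

    Sequences are visited longest-first (ties by lexicographic id); each
    joins the first existing representative, in representative creation
    order, with which its global identity is >= *threshold*; otherwise
    it founds a new cluster.  Deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not seqs:
        raise ValueError("cluster_sequences requires at least one sequence")
    ordered = sorted(seqs, key=lambda item: (-len(item[1]), item[0]))
    representatives: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    for seq_id, seq in ordered:
        placed = False
        for rep_id, rep_seq in representatives:
            if pairwise_identity(seq, rep_seq) >= threshold:
                members[rep_id].append(seq_id)
                placed = True
                break
        if not placed:
            representatives.append((seq_id, seq))
            members[seq_id] = [seq_id]
    return ClusterSet(
        threshold=threshold,
        clusters=tuple((rep_id, tuple(members[rep_id])) for rep_id, _ in representatives),
    )


def trim_alignment(
    alignment: Sequence[tuple[str, str]],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> TrimmedAlignment:
    """Keep exactly the columns whose non-gap fraction is >= *gap_threshold*."""
    if not alignment:
        raise ValueError("empty alignment")
    ids = tuple(seq_id for seq_id, _ in alignment)
    rows = [row for _, row in alignment]
    length = len(rows[0])
    if any(len(row) != length for row in rows):
        raise ValueError("alignment rows must all have equal length")
    n = len(rows)
    kept = [
        col
        for col in range(length)
        if sum(1 for row in rows if row[col] != "-") / n >= gap_threshold
    ]
    if not kept:
        raise ValueError(
            "all alignment columns were removed; lower gap_threshold to retain sparser columns"
        )
    trimmed_rows = tuple("".join(row[col] for col in kept) for row in rows)
    return TrimmedAlignment(sequence_ids=ids, kept_columns=tuple(kept), rows=trimmed_rows)


def assign_form(
    sequence: str,
    panel: ReferencePanel,
    genome_id: str = "",
    protein_id: str = "",
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    margin_floor: float = DEFAULT_MARGIN_FLOOR,
) -> RbcLAssignment:
    """Call the RubisCO form of one sequence by nearest panel reference.

    The nearest reference (highest global identity; exact identity ties
    yield UNASSIGNED) lends its form label when identity >=
    *identity_floor* and the identity gap to the best reference of any
    other form is >= *margin_floor*; otherwise the call is UNASSIGNED.
    Sequences shorter than 100 residues are never assigned.
    """
    if len(sequence) < MIN_ASSIGNABLE_LENGTH:
        logger.warning(
            "sequence %s/%s is shorter than %d residues; form left UNASSIGNED",
            genome_id,
            protein_id,
            MIN_ASSIGNABLE_LENGTH,
        )
        return RbcLAssignment(genome_id, protein_id, FormLabel.UNASSIGNED, "", 0.0, 0.0)
    identities = [(pairwise_identity(sequence, entry.sequence), entry) for entry in panel]
    identities.sort(key=lambda pair: (-pair[0], pair[1].ref_id))
    best_identity, best_entry = identities[0]
    tied = any(
        ident == best_identity and entry.form != best_entry.form
        for ident, entry in identities[1:]
    )
    best_other = max(
        (ident for ident, entry in identities if entry.form != best_entry.form),
        default=0.0,
    )
    margin = best_identity - best_other
    form = best_entry.form
    if tied or best_identity < identity_floor or margin < margin_floor:
        form = FormLabel.UNASSIGNED
    return RbcLAssignment(
        genome_id=genome_id,
        protein_id=protein_id,
        form=form,
        nearest_ref_id=best_entry.ref_id,
        identity_to_nearest=best_identity,
        margin=margin,
    )


def detect_rbcs(
    genome: GenomeRecord,
    rbcl_hit: MarkerHit,
    rbcs_hits: Sequence[MarkerHit],
    window: int = DEFAULT_COLOCALIZATION_WINDOW,
) -> tuple[bool, bool]:
    """rbcS presence anywhere in the genome, and colocalization near rbcL.

    Colocalized means some rbcS hit lies within *window* ordinal loci of
    the rbcL gene (strand-agnostic; inputs are ordered protein lists).
    """
    loci = {p.protein_id: p.locus_index for p in genome.proteins}
    if rbcl_hit.genome_id != genome.genome_id:
        raise ValueError("rbcL hit belongs to a different genome")
    relevant = [h for h in rbcs_hits if h.genome_id == genome.genome_id]
    present = bool(relevant)
    rbcl_locus = loci.get(rbcl_hit.protein_id)
    colocalized = any(
        rbcl_locus is not None
        and h.protein_id in loci
        and abs(loci[h.protein_id] - rbcl_locus) <= window
        for h in relevant
    )
    return present, colocalized


def nj_from_distances(ids: Sequence[str], matrix: np.ndarray) -> DistanceTree:
    """Neighbor-joining on a precomputed distance matrix.

    Negative branch-length estimates are clamped to zero (logged by the
    underlying implementation as ``neg_as_zero``).  Leaves are sorted by
    id before agglomeration so the result is deterministic.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("neighbor-joining requires at least 3 sequences")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    matrix = np.asarray(matrix, dtype=float)[np.ix_(order, order)]
    sorted_ids = [ids[i] for i in order]
    tree = nj(DistanceMatrix(matrix, ids=sorted_ids), neg_as_zero=True)
    newick = str(tree).strip()
    return DistanceTree(leaves=tuple(sorted_ids), newick=newick)


def mutual_alignment(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Progressive multiple alignment of protein sequences (BLOSUM62)."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    if len(seqs) < 2:
        raise ValueError("mutual alignment requires at least 2 sequences")
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    sequences = [bseq.ProteinSequence(seq) for _, seq in seqs]
    alignment = balign.align_multiple(sequences, matrix, gap_penalty=(-11, -1))[0]
    rows = []
    for (seq_id, _), symbols in zip(seqs, balign.get_symbols(alignment)):
        rows.append((seq_id, "".join("-" if s is None else s for s in symbols)))
    return rows


def build_nj_tree(
    seqs: Sequence[tuple[str, str]],
    panel: ReferencePanel | None = None,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> DistanceTree:
    """NJ tree over query sequences merged with an optional reference panel.

    Pipeline: progressive mutual alignment, gap-threshold trimming,
    distances = 1 - pairwise identity on the trimmed alignment, then
    neighbor-joining with negative branch lengths clamped to zero.
    """
    merged = list(seqs)
    if panel is not None:
        merged.extend((entry.ref_id, entry.sequence) for entry in panel)
    if len(merged) < 3:
        raise ValueError("build_nj_tree requires at least 3 sequences (queries + panel)")
    if len({seq_id for seq_id, _ in merged}) != len(merged):
        raise ValueError("duplicate sequence ids in tree input")
    trimmed = trim_alignment(mutual_alignment(merged), gap_threshold=gap_threshold)
    n = len(trimmed.rows)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - aligned_identity_rows(trimmed.rows[i], trimmed.rows[j])
            matrix[i, j] = matrix[j, i] = d
    return nj_from_distances(trimmed.sequence_ids, matrix)


def write_alignment_fasta(alignment: Sequence[tuple[str, str]] | TrimmedAlignment, path: str | Path) -> None:
    """Export a (possibly trimmed) alignment for external ML tree tools."""
    if isinstance(alignment, TrimmedAlignment):
        alignment = list(zip(alignment.sequence_ids, alignment.rows))
    with open(path, "w", encoding="utf-8") as handle:
        for seq_id, row in alignment:
            handle.write(f">{seq_id}\n{row}\n")


@dataclass(frozen=True)
class StrainEntry:
    """Minimal per-strain metadata for representative selection."""

    genome_id: str
    strain_label: str
    genus: str
    evidence_autotrophy: bool


def select_representatives(entries: Iterable[StrainEntry]) -> list[str]:
    """Pick genomes for phylogenetic analysis, genus by genus.

    Genera with at least one strain with demonstrated autotrophic growth
    contribute exactly one genome (the lexicographically smallest
    strain_label); genera lacking such evidence contribute every
    genome.  Strains without a genus are excluded with a warning.
    """
    by_genus: dict[str, list[StrainEntry]] = {}
    for entry in entries:
        if not entry.genus:
            logger.warning("strain %s has no genus; excluded from representative selection", entry.genome_id)
            continue
        by_genus.setdefault(entry.genus, []).append(entry)
    selected: list[str] = []
    for genus in sorted(by_genus):
        strains = sorted(by_genus[genus], key=lambda e: (e.strain_label, e.genome_id))
        if any(e.evidence_autotrophy for e in strains):
            selected.append(strains[0].genome_id)
        else:
            selected.extend(e.genome_id for e in strains)
    return selected


def annotate_rbcs(
    assignment: RbcLAssignment,
    present: bool,
    colocalized: bool,
) -> RbcLAssignment:
    """Return a copy of *assignment* with the rbcS flags filled in."""
    return replace(assignment, rbcs_present=present, rbcs_colocalized=colocalized)


def write_assignments_tsv(assignments: Sequence[RbcLAssignment], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "genome_id",
                "protein_id",
                "form",
                "nearest_ref",
                "identity",
                "margin",
                "rbcs_present",
                "rbcs_colocalized",
            ]
        )
        for a in assignments:
            writer.writerow(
                [
                    a.genome_id,
                    a.protein_id,
                    a.form.value,
                    a.nearest_ref_id,
                    f"{a.identity_to_nearest:.6f}",
                    f"{a.margin:.6f}",
                    a.rbcs_present,
                    a.rbcs_colocalized,
                ]
            )
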
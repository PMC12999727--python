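"""Marker catalog and similarity-based marker assignment.

The catalog holds one entry per functional marker gene (CBB-cycle steps,
hydrogenase groups, terminal oxidases, sox system, sqr, nar, puf, rbcS),
each backed by curated seed protein sequences and identity/coverage
thresholds.  ``search_markers`` assigns markers to the proteins of a
genome by global-alignment similarity against those seeds, producing the
same kind of table a profile-HMM annotation pipeline would emit.

The bundled default catalog is a synthetic stand-in: its seed sequences
are deterministic constructs that emulate the divergence structure of
the real marker families (see ``data/synthetic_marker_seeds.yaml``), not
database proteins.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from ._align import (
    align_score,
    align_stats,
    is_valid_protein,
    kmer_set,
    shares_kmers,
)

logger = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {
        "cbb",
        "hydrogenase",
        "oxidase",
        "sulfur_ox",
        "sulfur_red",
        "nitrate_red",
        "photosystem",
        "rubisco_small",
    }
)

#: markers that any usable catalog must define (CBB steps, donor/acceptor
#: rule genes, photosystem genes, rbcS, and the uptake-relevant
#: hydrogenase groups plus two non-uptake outgroups).
MANDATORY_MARKERS = (
    "K00855",  # PRK (prkB)
    "K01601",  # rbcL / cbbL
    "K00927",  # PGK
    "K05298",  # GAPA
    "K00150",  # gap2 / gapB
    "K00134",  # GAPDH / gapA
    "rbcS",
    "soxA",
    "soxB",
    "soxX",
    "soxY",
    "soxZ",
    "sqr",
    "dsrA",
    "dsrB",
    "narG",
    "narH",
    "pufL",
    "pufM",
    "coxA",
    "coxB",
    "cyoA",
    "cyoB",
    "cyoC",
    "cyoD",
    "ccoN",
    "ccoO",
    "cydA",
    "cydB",
    "hydrogenase:NiFe:1",
    "hydrogenase:NiFe:2a",
    "hydrogenase:NiFe:2b",
    "hydrogenase:NiFe:2c",
    "hydrogenase:NiFe:2d",
    "hydrogenase:NiFe:2e",
    "hydrogenase:NiFe:3b",
    "hydrogenase:NiFe:4h",
    "hydrogenase:NiFe:4i",
    "hydrogenase:FeFe:A1",
    "hydrogenase:FeFe:A2",
    "hydrogenase:FeFe:A3",
)

DEFAULT_MIN_IDENTITY = 0.40
DEFAULT_MIN_COVERAGE = 0.70


@dataclass(frozen=True)
class SeedSequence:
    label: str
    sequence: str
    provenance: str = ""


@dataclass(frozen=True)
class MarkerDef:
    """One marker gene with its seed sequences and acceptance thresholds."""

    marker_id: str
    category: str
    seeds: tuple[SeedSequence, ...]
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown marker category {self.category!r}")
        if not self.seeds:
            raise ValueError(f"marker {self.marker_id} has no seed sequences")
        for bound, name in ((self.min_identity, "min_identity"), (self.min_coverage, "min_coverage")):
            if not 0.0 < bound <= 1.0:
                raise ValueError(f"marker {self.marker_id}: {name} must be in (0, 1], got {bound}")
        for seed in self.seeds:
            if not is_valid_protein(seed.sequence):
                raise ValueError(f"marker {self.marker_id}: seed {seed.label} has an invalid sequence")


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein with its ordinal position along the genome."""

    protein_id: str
    sequence: str
    locus_index: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        if "-" in self.sequence:
            raise ValueError(f"protein {self.protein_id}: gap characters not allowed")
        if self.locus_index < 0:
            raise ValueError(f"protein {self.protein_id}: negative locus index")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome's identity, taxonomy, and ordered protein complement."""

    genome_id: str
    strain_label: str = ""
    taxonomy: tuple[str, str, str, str, str] = ("", "", "", "", "")  # phylum, class, order, genus, species
    proteins: tuple[ProteinRecord, ...] = ()

    def __post_init__(self) -> None:
        indices = [p.locus_index for p in self.proteins]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"genome {self.genome_id}: locus indices must be strictly increasing")


@dataclass(frozen=True)
class MarkerHit:
    """Assignment of one catalog marker to one protein."""

    genome_id: str
    protein_id: str
    marker_id: str
    best_seed_label: str
    identity: float
    coverage: float
    score: float
    provenance: str = "search"  # "search" or "imported"


class MarkerCatalog:
    """An ordered, id-unique collection of :class:`MarkerDef`."""

    def __init__(self, markers: Iterable[MarkerDef], require_mandatory: bool = True):
        self._markers: dict[str, MarkerDef] = {}
        for marker in markers:
            if marker.marker_id in self._markers:
                raise ValueError(f"duplicate marker_id {marker.marker_id!r} in catalog")
            self._markers[marker.marker_id] = marker
        if not self._markers:
            raise ValueError("catalog defines no markers")
        if require_mandatory:
            missing = [m for m in MANDATORY_MARKERS if m not in self._markers]
            if missing:
                raise ValueError(f"catalog is missing mandatory markers: {', '.join(missing)}")

    def __iter__(self):
        return iter(self._markers.values())

    def __len__(self) -> int:
        return len(self._markers)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._markers

    def __getitem__(self, marker_id: str) -> MarkerDef:
        return self._markers[marker_id]

    def marker_ids(self) -> list[str]:
        return list(self._markers)


def _parse_catalog_mapping(data: dict, require_mandatory: bool) -> MarkerCatalog:
    entries = data.get("markers")
    if not entries:
        raise ValueError("catalog file defines no markers")
    markers = []
    for entry in entries:
        seeds = tuple(
            SeedSequence(
                label=str(s["label"]),
                sequence=str(s["sequence"]).upper(),
                provenance=str(s.get("provenance", "")),
            )
            for s in entry.get("seeds", [])
        )
        markers.append(
            MarkerDef(
                marker_id=str(entry["marker_id"]),
                category=str(entry["category"]),
                seeds=seeds,
                min_identity=float(entry.get("min_identity", DEFAULT_MIN_IDENTITY)),
                min_coverage=float(entry.get("min_coverage", DEFAULT_MIN_COVERAGE)),
            )
        )
    return MarkerCatalog(markers, require_mandatory=require_mandatory)


def load_catalog(path: str | Path, require_mandatory: bool = True) -> MarkerCatalog:
    """Load a marker catalog from a YAML (or JSON) file.

    Raises ``ValueError`` on duplicate marker ids, empty files, or (by
    default) if any mandatory marker is absent.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"catalog file {path} is empty or malformed")
    return _parse_catalog_mapping(data, require_mandatory)


def default_catalog() -> MarkerCatalog:
    """The bundled synthetic seed catalog (every mandatory marker present)."""
    ref = resources.files("rubiscan.data") / "synthetic_marker_seeds.yaml"
    data = yaml.safe_load(ref.read_text())
    return _parse_catalog_mapping(data, require_mandatory=True)


def _best_seed(protein: str, marker: MarkerDef, protein_kmers, prescreen: bool):
    """Best seed of *marker* for *protein* by score, ties to the
    lexicographically smallest seed label; returns None if prescreened out."""
    best = None
    best_score = None
    for seed in sorted(marker.seeds, key=lambda s: s.label):
        # a protein much shorter than the seed can never reach coverage
        if len(protein) < marker.min_coverage * len(seed.sequence):
            continue
        if prescreen and not shares_kmers(protein_kmers, kmer_set(seed.sequence)):
            continue
        score = align_score(protein, seed.sequence)
        if best_score is None or score > best_score:
            best, best_score = seed, score
    return best


def search_markers(
    genome: GenomeRecord,
    catalog: MarkerCatalog,
    prescreen: bool = True,
) -> list[MarkerHit]:
    """Assign catalog markers to a genome's proteins by similarity.

    Each protein receives at most one hit per marker category (the
    highest-scoring marker whose thresholds it satisfies); distinct
    proteins may hit the same marker, so genuine multi-copy genes are
    retained.  Proteins containing characters outside the 20+X alphabet
    are skipped with a warning.  Output is deterministic and, up to
    ordering, invariant to protein order.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    hits: list[MarkerHit] = []
    for protein in genome.proteins:
        if not is_valid_protein(protein.sequence):
            logger.warning(
                "genome %s: protein %s contains characters outside the amino-acid alphabet; skipped",
                genome.genome_id,
                protein.protein_id,
            )
            continue
        protein_kmers = kmer_set(protein.sequence)
        best_per_category: dict[str, MarkerHit] = {}
        for marker in catalog:
            seed = _best_seed(protein.sequence, marker, protein_kmers, prescreen)
            if seed is None:
                continue
            stats = align_stats(protein.sequence, seed.sequence)
            if stats.identity < marker.min_identity or stats.coverage < marker.min_coverage:
                continue
            hit = MarkerHit(
                genome_id=genome.genome_id,
                protein_id=protein.protein_id,
                marker_id=marker.marker_id,
                best_seed_label=seed.label,
                identity=stats.identity,
                coverage=stats.coverage,
                score=stats.score,
            )
            incumbent = best_per_category.get(marker.category)
            if incumbent is None or hit.score > incumbent.score or (
                hit.score == incumbent.score and hit.marker_id < incumbent.marker_id
            ):
                best_per_category[marker.category] = hit
        hits.extend(sorted(best_per_category.values(), key=lambda h: h.marker_id))
    return hits


def read_annotation_table(
    path: str | Path,
    catalog: MarkerCatalog,
    on_unknown_marker: str = "warn",
) -> list[MarkerHit]:
    """Read precomputed marker annotations from a TSV file.

    The table must carry a header with at least ``genome_id``,
    ``protein_id`` and ``marker_id``; ``identity`` and ``coverage``
    columns are optional and default to the sentinel 1.0 with
    provenance ``"imported"``.  Rows naming a marker absent from the
    catalog are dropped with a warning, or raise if
    ``on_unknown_marker="error"``.
    """
    if on_unknown_marker not in ("warn", "error"):
        raise ValueError("on_unknown_marker must be 'warn' or 'error'")
    hits: list[MarkerHit] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"genome_id", "protein_id", "marker_id"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"annotation table {path} must have columns {sorted(required)}")
        for row in reader:
            marker_id = row["marker_id"]
            if marker_id not in catalog:
                if on_unknown_marker == "error":
                    raise ValueError(f"annotation table row names unknown marker {marker_id!r}")
                logger.warning("annotation table: unknown marker %r; row dropped", marker_id)
                continue
            hits.append(
                MarkerHit(
                    genome_id=row["genome_id"],
                    protein_id=row["protein_id"],
                    marker_id=marker_id,
                    best_seed_label=row.get("seed") or "",
                    identity=float(row["identity"]) if row.get("identity") else 1.0,
                    coverage=float(row["coverage"]) if row.get("coverage") else 1.0,
                    score=float(row["score"]) if row.get("score") else 0.0,
                    provenance="imported",
                )
            )
    return hits


def write_hits_tsv(hits: Sequence[MarkerHit], path: str | Path) -> None:
    """Write marker hits as UTF-8 TSV with one header line."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome_id", "protein_id", "marker_id", "seed", "identity", "coverage", "score"])
        for hit in hits:
            writer.writerow(
                [
                    hit.genome_id,
                    hit.protein_id,
                    hit.marker_id,
                    hit.best_seed_label,
                    f"{hit.identity:.6f}",
                    f"{hit.coverage:.6f}",
                    f"{hit.score:.1f}",
                ]
            )


def read_protein_fasta(path: str | Path, genome_id: str | None = None) -> list[GenomeRecord]:
    """Read protein FASTA into genome records.

    With ``genome_id`` given, all sequences belong to that genome.
    Otherwise headers are expected as ``<genome_id>|<protein_id>`` and a
    record is produced per genome prefix, proteins in file order.
    """
    from Bio import SeqIO

    by_genome: dict[str, list[ProteinRecord]] = {}
    for idx, record in enumerate(SeqIO.parse(str(path), "fasta")):
        if genome_id is not None:
            gid, pid = genome_id, record.id
        elif "|" in record.id:
            gid, pid = record.id.split("|", 1)
        else:
            raise ValueError(
                f"FASTA header {record.id!r} lacks a '<genome_id>|<protein_id>' prefix and no genome_id was given"
            )
        proteins = by_genome.setdefault(gid, [])
        proteins.append(ProteinRecord(protein_id=pid, sequence=str(record.seq).upper(), locus_index=len(proteins)))
    return [
        GenomeRecord(genome_id=gid, strain_label=gid, proteins=tuple(proteins))
        for gid, proteins in by_genome.items()
    ]
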
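"""Synthetic proteomes with known ground truth.

Generates small genomes whose protein complements encode a chosen truth:
which CBB-cycle steps are present, which RubisCO form(s) the rbcL copies
belong to (emitted as mutants of reference-panel entries at a controlled
target identity), whether and where rbcS sits relative to rbcL, and
which donor/acceptor/photosystem marker genes exist.  Decoy proteins
(residue-shuffled seeds) pad each proteome.  Every pipeline stage can
then be benchmarked for exact recovery without any external data.

The mutation model is deliberately non-phylogenetic: substitutions are
drawn uniformly over the 19 alternative residues and indels are off by
default (an optional indel mode exists), so target identities are clean.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._align import AMINO_ACIDS, pairwise_identity
from .markers import GenomeRecord, MarkerCatalog, ProteinRecord
from .rbcl_phylo import FormLabel, ReferencePanel
from .reporting import ENVIRONMENTS, StrainMetadata
from .trait_engine import SOX_COMPLETE, SOX_PARTIAL, TraitProfile

MIN_TARGET_IDENTITY = 0.3

#: gene sets emitted per sulfur-oxidation truth state
_SOX_GENES = {
    "complete_sox": tuple(sorted(SOX_COMPLETE)),
    "partial_sox_lacking_soxB": tuple(sorted(SOX_PARTIAL)),
    "sqr_only": ("sqr",),
    "none": (),
}

AEROBIC_GENE_SETS = (("coxA", "coxB"), ("cyoA", "cyoB", "cyoC", "cyoD"))
MICROAEROPHILIC_GENE_SETS = (("ccoN", "ccoO"), ("cydA", "cydB"))
UPTAKE_HYDROGENASES = ("NiFe:1", "NiFe:2a", "NiFe:2b", "NiFe:2c", "NiFe:2d", "NiFe:2e", "NiFe:4h", "NiFe:4i", "FeFe:A2", "FeFe:A3")
NON_UPTAKE_HYDROGENASES = ("NiFe:3b", "FeFe:A1")


def mutate_sequence(
    seed_seq: str,
    target_identity: float,
    rng: np.random.Generator,
    verify: bool = True,
    indel_rate: float = 0.0,
) -> str:
    """Mutate *seed_seq* to approximately *target_identity*.

    Exactly ``round((1 - target) * L)`` positions are substituted, each
    to a residue drawn uniformly from the 19 alternatives, so the
    ungapped identity hits the target by construction; with
    ``verify=True`` the realized global-alignment identity is checked to
    lie within +/-0.02 of the target.  ``indel_rate`` > 0 additionally
    inserts/deletes short geometric-length segments (identity targets
    are then only approximate; verification still applies).
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError(f"target identity must be in (0, 1], got {target_identity}")
    if target_identity < MIN_TARGET_IDENTITY:
        raise ValueError(
            f"target identity {target_identity} is below the classifier validity range (>= {MIN_TARGET_IDENTITY})"
        )
    residues = list(seed_seq)
    n_sub = round((1.0 - target_identity) * len(residues))
    if n_sub > 0:
        positions = rng.choice(len(residues), size=n_sub, replace=False)
        for position in positions:
            alternatives = AMINO_ACIDS.replace(residues[position], "")
            residues[position] = alternatives[rng.integers(len(alternatives))]
    if indel_rate > 0.0:
        out = []
        for residue in residues:
            roll = rng.random()
            if roll < indel_rate / 2.0:
                continue  # deletion
            out.append(residue)
            if roll > 1.0 - indel_rate / 2.0:
                length = rng.geometric(0.5)
                out.extend(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))
        residues = out if out else residues
    mutated = "".join(residues)
    if verify and indel_rate == 0.0:
        realized = pairwise_identity(mutated, seed_seq)
        if abs(realized - target_identity) > 0.02:
            raise AssertionError(
                f"realized identity {realized:.3f} deviates from target {target_identity:.3f} by more than 0.02"
            )
    return mutated


def shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    """Residue-shuffled copy of a sequence (decoy with identical composition)."""
    permutation = rng.permutation(len(sequence))
    return "".join(sequence[i] for i in permutation)


@dataclass(frozen=True)
class GenomeTruth:
    """The intended content and traits of one synthetic genome."""

    genome_id: str
    domain: str = "bacteria"
    phylum: str = "Synthetica"
    order: str = "Synthetales"
    genus: str = "Simulogenus"
    environment: str = "unknown"
    forms: tuple[FormLabel, ...] = ()
    target_identity: float = 0.85
    rbcs_present: bool = False
    rbcs_offset: int = 1
    has_prk: bool = True
    has_pgk: bool = True
    gap_marker: str | None = "K00134"  # one of the three GAP alternatives, or None
    hydrogenase_groups: tuple[str, ...] = ()  # e.g. ("NiFe:1",)
    sulfur_oxidation: str = "none"
    aerobic_genes: tuple[str, ...] = ()
    microaerophilic_genes: tuple[str, ...] = ()
    nitrate_reduction: bool = False
    sulfur_reduction: bool = False
    photosystem: bool = False
    n_decoys: int = 8

    @property
    def cbb_complete(self) -> bool:
        return self.has_prk and bool(self.forms) and self.has_pgk and self.gap_marker is not None

    def expected_profile(self) -> TraitProfile:
        """The trait profile a perfect annotation of this genome yields."""
        h2 = any(group in UPTAKE_HYDROGENASES for group in self.hydrogenase_groups)
        return TraitProfile(
            genome_id=self.genome_id,
            h2_uptake=h2,
            sulfur_oxidation=self.sulfur_oxidation,
            oxygen_aerobic_lowaff=bool(self.aerobic_genes),
            oxygen_microaerophilic_highaff=bool(self.microaerophilic_genes),
            nitrate_reduction=self.nitrate_reduction,
            sulfur_reduction=self.sulfur_reduction,
            photosystem_ii=self.photosystem,
            forms_present=frozenset(f for f in self.forms if f != FormLabel.UNASSIGNED),
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """A reproducible collection of genome truths."""

    genomes: tuple[GenomeTruth, ...]
    rng_seed: int = 0

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)


@dataclass
class GroundTruth:
    """What was actually emitted, keyed by genome."""

    truths: dict[str, GenomeTruth]
    roles: dict[str, dict[str, str]]  # genome_id -> protein_id -> role ("marker:<id>", "rbcL:<form>", "decoy")

    def to_json(self) -> dict:
        return {
            "truths": {gid: {**asdict(t), "forms": [f.value for f in t.forms]} for gid, t in self.truths.items()},
            "roles": self.roles,
        }


def _marker_seed(catalog: MarkerCatalog, marker_id: str) -> str:
    marker = catalog[marker_id]
    return min(marker.seeds, key=lambda s: s.label).sequence


def _panel_seed(panel: ReferencePanel, form: FormLabel) -> str:
    entries = sorted((e for e in panel if e.form == form), key=lambda e: e.ref_id)
    if not entries:
        raise ValueError(f"reference panel has no entry for requested form {form.value}")
    return entries[0].sequence


def generate(
    spec: SyntheticSpec,
    catalog: MarkerCatalog,
    panel: ReferencePanel,
    out_dir: str | Path | None = None,
) -> tuple[list[GenomeRecord], list[StrainMetadata], GroundTruth]:
    """Emit synthetic genomes, metadata and ground truth for a spec.

    Deterministic per ``spec.rng_seed``: running twice yields
    byte-identical outputs.  Raises if a truth is unsatisfiable (e.g. a
    form the panel lacks, or an unknown marker gene).
    """
    rng = np.random.default_rng(spec.rng_seed)
    genomes: list[GenomeRecord] = []
    metadata: list[StrainMetadata] = []
    roles: dict[str, dict[str, str]] = {}
    for truth in spec.genomes:
        if truth.sulfur_oxidation not in _SOX_GENES:
            raise ValueError(f"unknown sulfur_oxidation state {truth.sulfur_oxidation!r}")
        proteins: list[ProteinRecord] = []
        genome_roles: dict[str, str] = {}
        decoy_budget = truth.n_decoys

        def emit(sequence: str, role: str) -> None:
            pid = f"{truth.genome_id}_p{len(proteins):03d}"
            proteins.append(ProteinRecord(protein_id=pid, sequence=sequence, locus_index=len(proteins)))
            genome_roles[pid] = role

        def emit_marker_gene(marker_id: str) -> None:
            seed = _marker_seed(catalog, marker_id)
            emit(mutate_sequence(seed, truth.target_identity, rng, verify=False), f"marker:{marker_id}")

        def emit_decoy() -> None:
            template_marker = catalog.marker_ids()[rng.integers(len(catalog))]
            emit(shuffle_sequence(_marker_seed(catalog, template_marker), rng), "decoy")

        # donor/acceptor/CBB-step genes first, in a fixed order
        if truth.has_prk:
            emit_marker_gene("K00855")
        if truth.has_pgk:
            emit_marker_gene("K00927")
        if truth.gap_marker is not None:
            if truth.gap_marker not in ("K05298", "K00150", "K00134"):
                raise ValueError(f"gap_marker must be one of the GAP alternatives, got {truth.gap_marker!r}")
            emit_marker_gene(truth.gap_marker)
        for group in truth.hydrogenase_groups:
            emit_marker_gene(f"hydrogenase:{group}")
        for gene in _SOX_GENES[truth.sulfur_oxidation]:
            emit_marker_gene(gene)
        for gene in truth.aerobic_genes + truth.microaerophilic_genes:
            emit_marker_gene(gene)
        if truth.nitrate_reduction:
            emit_marker_gene("narG")
            emit_marker_gene("narH")
        if truth.sulfur_reduction:
            emit_marker_gene("dsrA")
            emit_marker_gene("dsrB")
        if truth.photosystem:
            emit_marker_gene("pufL")
            emit_marker_gene("pufM")

        # a couple of decoys between the trait block and the rbcL locus
        for _ in range(min(2, decoy_budget)):
            emit_decoy()
            decoy_budget -= 1

        # rbcL copies; rbcS placed at the requested offset from the first copy
        for copy_index, form in enumerate(truth.forms):
            seed = _panel_seed(panel, form)
            emit(mutate_sequence(seed, truth.target_identity, rng, verify=False), f"rbcL:{form.value}")
            if copy_index == 0 and truth.rbcs_present:
                if truth.rbcs_offset < 1:
                    raise ValueError("rbcs_offset must be >= 1")
                for _ in range(truth.rbcs_offset - 1):
                    if decoy_budget > 0:
                        emit_decoy()
                        decoy_budget -= 1
                    else:
                        emit_decoy()
                emit_marker_gene("rbcS")

        for _ in range(max(decoy_budget, 0)):
            emit_decoy()

        genomes.append(
            GenomeRecord(
                genome_id=truth.genome_id,
                strain_label=truth.genome_id,
                taxonomy=(truth.phylum, "", truth.order, truth.genus, ""),
                proteins=tuple(proteins),
            )
        )
        metadata.append(
            StrainMetadata(
                genome_id=truth.genome_id,
                phylum=truth.phylum,
                order=truth.order,
                genus=truth.genus,
                evidence="untested",
                environment=truth.environment,
            )
        )
        roles[truth.genome_id] = genome_roles

    ground_truth = GroundTruth(truths={t.genome_id: t for t in spec.genomes}, roles=roles)
    if out_dir is not None:
        _write_outputs(Path(out_dir), genomes, metadata, ground_truth)
    return genomes, metadata, ground_truth


def _write_outputs(
    out_dir: Path,
    genomes: Sequence[GenomeRecord],
    metadata: Sequence[StrainMetadata],
    ground_truth: GroundTruth,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "proteomes.fasta", "w", encoding="utf-8") as handle:
        for genome in genomes:
            for protein in genome.proteins:
                handle.write(f">{genome.genome_id}|{protein.protein_id}\n{protein.sequence}\n")
    with open(out_dir / "metadata.tsv", "w", encoding="utf-8") as handle:
        handle.write("genome_id\tphylum\torder\tgenus\tevidence\tenvironment\n")
        for m in metadata:
            handle.write(f"{m.genome_id}\t{m.phylum}\t{m.order}\t{m.genus}\t{m.evidence}\t{m.environment}\n")
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as handle:
        json.dump(ground_truth.to_json(), handle, indent=2, sort_keys=True)
        handle.write("\n")


def random_spec(
    n_genomes: int,
    rng_seed: int,
    target_identity: float = 0.85,
    forms: Sequence[FormLabel] | None = None,
    n_decoys: int = 8,
) -> SyntheticSpec:
    """Draw a varied, reproducible collection of genome truths.

    Every genome gets a complete CBB gene set and one rbcL copy of a
    cycling choice of form; donors, acceptors and photosystem states are
    sampled so that all rule branches are exercised across the batch.
    """
    rng = np.random.default_rng(rng_seed)
    if forms is None:
        forms = [f for f in FormLabel if f != FormLabel.UNASSIGNED]
    truths = []
    sox_states = list(_SOX_GENES)
    for index in range(n_genomes):
        form = forms[index % len(forms)]
        h2 = bool(rng.random() < 0.5)
        if h2:
            hydro: tuple[str, ...] = (UPTAKE_HYDROGENASES[rng.integers(len(UPTAKE_HYDROGENASES))],)
        elif rng.random() < 0.3:
            hydro = (NON_UPTAKE_HYDROGENASES[rng.integers(len(NON_UPTAKE_HYDROGENASES))],)
        else:
            hydro = ()
        aerobic = AEROBIC_GENE_SETS[rng.integers(len(AEROBIC_GENE_SETS))] if rng.random() < 0.5 else ()
        micro = MICROAEROPHILIC_GENE_SETS[rng.integers(len(MICROAEROPHILIC_GENE_SETS))] if rng.random() < 0.5 else ()
        truths.append(
            GenomeTruth(
                genome_id=f"SYN{index:03d}",
                forms=(form,),
                target_identity=target_identity,
                rbcs_present=form in (FormLabel.IA, FormLabel.IB, FormLabel.IC, FormLabel.ID, FormLabel.IE, FormLabel.I_THERMUS),
                rbcs_offset=int(rng.integers(1, 4)),
                gap_marker=("K05298", "K00150", "K00134")[index % 3],
                hydrogenase_groups=hydro,
                sulfur_oxidation=sox_states[int(rng.integers(len(sox_states)))],
                aerobic_genes=aerobic,
                microaerophilic_genes=micro,
                nitrate_reduction=bool(rng.random() < 0.5),
                sulfur_reduction=bool(rng.random() < 0.3),
                photosystem=bool(rng.random() < 0.3),
                environment=ENVIRONMENTS[int(rng.integers(len(ENVIRONMENTS)))],
                n_decoys=n_decoys,
            )
        )
    return SyntheticSpec(genomes=tuple(truths), rng_seed=rng_seed)
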
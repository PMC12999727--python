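"""Marker-presence rules for electron donors, acceptors, and phototrophy.

The rule set maps detected marker genes onto the physiology that a
screening study would predict for each genome:

* H2 as electron donor — any *uptake* hydrogenase: [NiFe] groups 1,
  2a-2e, 4h, 4i or [FeFe] groups A2, A3 (evolving/bifurcating groups
  such as NiFe 3b or FeFe A1 do not count).
* Sulfur species as donor — the thiosulfate-oxidation sox system
  (complete soxABXYZ, or the incomplete state lacking only soxB) or the
  sulfide oxidation gene sqr.
* Oxygen as acceptor — low-affinity "aerobic" A-family heme-copper
  oxidases (coxA+coxB or cyoABCD) vs high-affinity "microaerophilic"
  C-family (ccoN+ccoO) or cytochrome bd (cydA+cydB) oxidases.
* Nitrate as acceptor — respiratory nitrate reductase narG+narH.
* Sulfur species as acceptor — dissimilatory sulfite reductase
  dsrA+dsrB (catalog-overridable choice; the trait is reported at the
  gene-pair level).
* Phototrophy — both type-II reaction-center proteins PufL and PufM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cbb_rules import EligibilityVerdict
from .markers import MarkerCatalog, MarkerHit
from .rbcl_phylo import FormLabel, RbcLAssignment

UPTAKE_GROUPS = {
    "NiFe": frozenset({"1", "2a", "2b", "2c", "2d", "2e", "4h", "4i"}),
    "FeFe": frozenset({"A2", "A3"}),
}

SOX_COMPLETE = frozenset({"soxA", "soxB", "soxX", "soxY", "soxZ"})
SOX_PARTIAL = SOX_COMPLETE - {"soxB"}

SULFUR_OX_STATES = ("complete_sox", "partial_sox_lacking_soxB", "sqr_only", "none")


@dataclass(frozen=True)
class HydrogenaseCall:
    """Family/group assignment of one hydrogenase gene."""

    protein_id: str
    family: str  # "NiFe" or "FeFe"
    group: str

    @property
    def is_uptake(self) -> bool:
        return self.group in UPTAKE_GROUPS.get(self.family, frozenset())


@dataclass(frozen=True)
class TraitProfile:
    """Per-genome marker-derived physiology booleans/states."""

    genome_id: str
    h2_uptake: bool
    sulfur_oxidation: str  # one of SULFUR_OX_STATES
    oxygen_aerobic_lowaff: bool
    oxygen_microaerophilic_highaff: bool
    nitrate_reduction: bool
    sulfur_reduction: bool
    photosystem_ii: bool
    forms_present: frozenset[FormLabel] = frozenset()
    evidence: dict = field(default_factory=dict, compare=False)  # trait -> supporting marker ids


@dataclass(frozen=True)
class GrowthMode:
    """One predicted autotrophic growth configuration."""

    donor: str
    acceptor: str
    mode: str
    note: str = ""


def classify_hydrogenase(hit: MarkerHit, catalog: MarkerCatalog) -> HydrogenaseCall:
    """Resolve a hydrogenase marker hit into family and group.

    Group-labelled seeds back each hydrogenase marker, so the
    nearest-seed decision already happened in the similarity search;
    here the winning marker id (``hydrogenase:<family>:<group>``) is
    decoded and validated.
    """
    marker = catalog[hit.marker_id]
    if marker.category != "hydrogenase":
        raise ValueError(f"marker {hit.marker_id!r} is not a hydrogenase marker")
    try:
        _, family, group = hit.marker_id.split(":")
    except ValueError as exc:
        raise ValueError(
            f"hydrogenase marker id {hit.marker_id!r} is not of the form 'hydrogenase:<family>:<group>'"
        ) from exc
    if family not in ("NiFe", "FeFe"):
        raise ValueError(f"unknown hydrogenase family {family!r}")
    return HydrogenaseCall(protein_id=hit.protein_id, family=family, group=group)


def _sulfur_oxidation_state(present: set[str]) -> str:
    sox = present & SOX_COMPLETE
    if sox >= SOX_COMPLETE:
        return "complete_sox"
    if sox >= SOX_PARTIAL and "soxB" not in present:
        return "partial_sox_lacking_soxB"
    if "sqr" in present:
        return "sqr_only"
    return "none"


def infer_traits(
    hits: Iterable[MarkerHit],
    hydro_calls: Sequence[HydrogenaseCall],
    assignments: Sequence[RbcLAssignment],
    genome_id: str,
) -> TraitProfile:
    """Derive the trait profile of one genome from its marker hits."""
    present: set[str] = set()
    support: dict[str, list[str]] = {}
    for hit in hits:
        if hit.genome_id != genome_id:
            raise ValueError(f"hit for genome {hit.genome_id!r} passed to infer_traits({genome_id!r})")
        present.add(hit.marker_id)
    for assignment in assignments:
        if assignment.genome_id != genome_id:
            raise ValueError("assignment belongs to a different genome")

    aerobic = ({"coxA", "coxB"} <= present) or ({"cyoA", "cyoB", "cyoC", "cyoD"} <= present)
    microaerophilic = ({"ccoN", "ccoO"} <= present) or ({"cydA", "cydB"} <= present)
    sulfur_ox = _sulfur_oxidation_state(present)

    support["h2_uptake"] = sorted(
        {f"hydrogenase:{c.family}:{c.group}" for c in hydro_calls if c.is_uptake}
    )
    support["sulfur_oxidation"] = sorted(present & (SOX_COMPLETE | {"sqr"}))
    support["oxygen_aerobic_lowaff"] = sorted(present & {"coxA", "coxB", "cyoA", "cyoB", "cyoC", "cyoD"})
    support["oxygen_microaerophilic_highaff"] = sorted(present & {"ccoN", "ccoO", "cydA", "cydB"})
    support["nitrate_reduction"] = sorted(present & {"narG", "narH"})
    support["sulfur_reduction"] = sorted(present & {"dsrA", "dsrB"})
    support["photosystem_ii"] = sorted(present & {"pufL", "pufM"})

    return TraitProfile(
        genome_id=genome_id,
        h2_uptake=any(call.is_uptake for call in hydro_calls),
        sulfur_oxidation=sulfur_ox,
        oxygen_aerobic_lowaff=aerobic,
        oxygen_microaerophilic_highaff=microaerophilic,
        nitrate_reduction={"narG", "narH"} <= present,
        sulfur_reduction={"dsrA", "dsrB"} <= present,
        photosystem_ii={"pufL", "pufM"} <= present,
        forms_present=frozenset(a.form for a in assignments if a.form != FormLabel.UNASSIGNED),
        evidence=support,
    )


def predict_growth_modes(profile: TraitProfile, cbb: EligibilityVerdict) -> list[GrowthMode]:
    """Cross available electron donors with acceptors for eligible genomes.

    Chemolithoautotrophic modes are the donor x acceptor cross-product;
    a phototrophy mode is added when both PufL and PufM are present,
    always flagged with the aerobic-anoxygenic-phototroph caveat that
    CBB genes in phototrophs do not guarantee autotrophy, and with a
    redox-balance note when no chemical donor was detected.  Genomes
    that are not CBB-eligible get an empty list.
    """
    if profile.genome_id != cbb.genome_id:
        raise ValueError("profile and eligibility verdict describe different genomes")
    if not cbb.eligible:
        return []
    donors = []
    if profile.h2_uptake:
        donors.append("H2")
    if profile.sulfur_oxidation != "none":
        donors.append("sulfur_species")
    acceptors = []
    if profile.oxygen_aerobic_lowaff:
        acceptors.append("O2_aerobic")
    if profile.oxygen_microaerophilic_highaff:
        acceptors.append("O2_microaerophilic")
    if profile.nitrate_reduction:
        acceptors.append("nitrate")
    if profile.sulfur_reduction:
        acceptors.append("sulfur_species")
    modes = [
        GrowthMode(donor=d, acceptor=a, mode="chemolithoautotrophy")
        for d in donors
        for a in acceptors
    ]
    if profile.photosystem_ii:
        note = "CBB-not-necessarily-autotrophic"
        if not donors:
            note += "; no electron donor detected - CBB cycle may serve intracellular redox balance"
        modes.append(GrowthMode(donor="light", acceptor="", mode="phototrophy", note=note))
    return modes


def write_traits_tsv(profiles: Sequence[TraitProfile], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "genome_id",
                "h2_uptake",
                "sulfur_oxidation",
                "oxygen_aerobic_lowaff",
                "oxygen_microaerophilic_highaff",
                "nitrate_reduction",
                "sulfur_reduction",
                "photosystem_ii",
                "forms_present",
            ]
        )
        for p in profiles:
            writer.writerow(
                [
                    p.genome_id,
                    p.h2_uptake,
                    p.sulfur_oxidation,
                    p.oxygen_aerobic_lowaff,
                    p.oxygen_microaerophilic_highaff,
                    p.nitrate_reduction,
                    p.sulfur_reduction,
                    p.photosystem_ii,
                    ",".join(sorted(f.value for f in p.forms_present)),
                ]
            )


def read_traits_tsv(path) -> list[TraitProfile]:
    """Read per-genome trait profiles written by :func:`write_traits_tsv`."""
    import csv

    def as_bool(value: str) -> bool:
        return value.strip().lower() == "true"

    profiles = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            forms = frozenset(
                FormLabel(v) for v in row["forms_present"].split(",") if v.strip()
            )
            profiles.append(
                TraitProfile(
                    genome_id=row["genome_id"],
                    h2_uptake=as_bool(row["h2_uptake"]),
                    sulfur_oxidation=row["sulfur_oxidation"],
                    oxygen_aerobic_lowaff=as_bool(row["oxygen_aerobic_lowaff"]),
                    oxygen_microaerophilic_highaff=as_bool(row["oxygen_microaerophilic_highaff"]),
                    nitrate_reduction=as_bool(row["nitrate_reduction"]),
                    sulfur_reduction=as_bool(row["sulfur_reduction"]),
                    photosystem_ii=as_bool(row["photosystem_ii"]),
                    forms_present=forms,
                )
            )
    return profiles


def traits_json(profiles: Sequence[TraitProfile]) -> list[dict]:
    """JSON-ready per-genome traits with the supporting-marker evidence trace."""
    return [
        {
            "genome_id": p.genome_id,
            "h2_uptake": p.h2_uptake,
            "sulfur_oxidation": p.sulfur_oxidation,
            "oxygen_aerobic_lowaff": p.oxygen_aerobic_lowaff,
            "oxygen_microaerophilic_highaff": p.oxygen_microaerophilic_highaff,
            "nitrate_reduction": p.nitrate_reduction,
            "sulfur_reduction": p.sulfur_reduction,
            "photosystem_ii": p.photosystem_ii,
            "forms_present": sorted(f.value for f in p.forms_present),
            "evidence": p.evidence,
        }
        for p in profiles
    ]
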
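"""End-to-end per-genome analysis: markers -> CBB -> forms -> traits."""

from __future__ import annotations

from dataclasses import dataclass

from .cbb_rules import CBBStatus, EligibilityVerdict, evaluate_cbb, evaluate_eligibility
from .markers import GenomeRecord, MarkerCatalog, MarkerHit, search_markers
from .rbcl_phylo import (
    RbcLAssignment,
    ReferencePanel,
    annotate_rbcs,
    assign_form,
    detect_rbcs,
)
from .trait_engine import (
    GrowthMode,
    HydrogenaseCall,
    TraitProfile,
    classify_hydrogenase,
    infer_traits,
    predict_growth_modes,
)


@dataclass(frozen=True)
class GenomeAnalysis:
    """Everything the pipeline derives for one genome."""

    genome_id: str
    hits: tuple[MarkerHit, ...]
    cbb: CBBStatus
    assignments: tuple[RbcLAssignment, ...]
    hydrogenases: tuple[HydrogenaseCall, ...]
    traits: TraitProfile
    eligibility: EligibilityVerdict
    growth_modes: tuple[GrowthMode, ...]


def analyze_genome(
    genome: GenomeRecord,
    catalog: MarkerCatalog,
    panel: ReferencePanel,
    domain: str = "bacteria",
    prescreen: bool = True,
) -> GenomeAnalysis:
    """Run the whole marker/CBB/form/trait pipeline on one genome."""
    hits = search_markers(genome, catalog, prescreen=prescreen)
    cbb = evaluate_cbb(hits, genome.genome_id)
    sequences = {p.protein_id: p.sequence for p in genome.proteins}
    rbcl_hits = [h for h in hits if h.marker_id == "K01601"]
    rbcs_hits = [h for h in hits if h.marker_id == "rbcS"]
    assignments = []
    for hit in rbcl_hits:
        assignment = assign_form(
            sequences[hit.protein_id], panel, genome_id=genome.genome_id, protein_id=hit.protein_id
        )
        present, colocalized = detect_rbcs(genome, hit, rbcs_hits)
        assignments.append(annotate_rbcs(assignment, present, colocalized))
    hydro_calls = tuple(
        classify_hydrogenase(h, catalog) for h in hits if catalog[h.marker_id].category == "hydrogenase"
    )
    traits = infer_traits(hits, hydro_calls, assignments, genome.genome_id)
    eligibility = evaluate_eligibility(cbb, assignments, domain=domain)
    modes = tuple(predict_growth_modes(traits, eligibility))
    return GenomeAnalysis(
        genome_id=genome.genome_id,
        hits=tuple(hits),
        cbb=cbb,
        assignments=tuple(assignments),
        hydrogenases=hydro_calls,
        traits=traits,
        eligibility=eligibility,
        growth_modes=modes,
    )
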
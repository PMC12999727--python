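"""Predict autotrophic growth modes from marker presence.

Simulates a genome carrying an uptake [NiFe]-hydrogenase, narG/narH and
an A-family terminal oxidase alongside a complete CBB gene set, then
crosses its electron donors with acceptors.
"""

from rubiscan import (
    FormLabel,
    GenomeTruth,
    SyntheticSpec,
    analyze_genome,
    default_catalog,
    default_panel,
    generate,
)

catalog = default_catalog()
panel = default_panel()

truth = GenomeTruth(
    genome_id="knallgas",
    forms=(FormLabel.IE,),
    hydrogenase_groups=("NiFe:2a",),
    aerobic_genes=("coxA", "coxB"),
    nitrate_reduction=True,
)
genomes, _, _ = generate(SyntheticSpec(genomes=(truth,), rng_seed=5), catalog, panel)
analysis = analyze_genome(genomes[0], catalog, panel)

traits = analysis.traits
print(f"genome {analysis.genome_id}: CBB complete={analysis.cbb.complete}, eligible={analysis.eligibility.eligible}")
print(f"  H2 uptake: {traits.h2_uptake}  (hydrogenase groups: "
      f"{[f'{c.family}:{c.group}' for c in analysis.hydrogenases]})")
print(f"  aerobic oxidase: {traits.oxygen_aerobic_lowaff}  nitrate reduction: {traits.nitrate_reduction}")
print("\npredicted growth modes (donor x acceptor):")
for mode in analysis.growth_modes:
    print(f"  {mode.donor} -> {mode.acceptor}  [{mode.mode}]")
print("\nEach line is one feasible chemolithoautotrophic configuration:")
print("hydrogen oxidation with O2 under aerobic conditions, or with nitrate anaerobically.")
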
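# rubiscan

Genome-based prediction of CO₂-fixation potential through the
Calvin–Benson–Bassham (CBB) cycle in bacteria and archaea.

Culture collections hold thousands of genome-sequenced strains whose
autotrophic capabilities have never been tested in the laboratory.
`rubiscan` screens protein complements for the genetic capacity to fix
CO₂ via the CBB cycle and predicts the growth conditions under which
that capacity could be expressed, so that microbiologists can shortlist
candidate autotrophs for cultivation experiments.

## What it computes

**CBB completeness.** A genome is a CBB candidate when it carries all
four marker steps of the reductive pentose-phosphate module:
phosphoribulokinase (PRK, K00855), the RubisCO large subunit (RbcL,
K01601), phosphoglycerate kinase (PGK, K00927), and any of the three
glyceraldehyde-3-phosphate dehydrogenase alternatives (K05298, K00150,
K00134).

**RubisCO form classification.** RbcL copies are assigned to the form
clades IA–IE, the *Thermus* clade, the small-subunit-lacking variants
I′, I″, I-α and I-Anaero, II, III, or the non-carboxylating
RubisCO-like form IV, by nearest-reference global-alignment identity
against a labelled panel (call floors: identity ≥ 0.45, margin to the
best other-form reference ≥ 0.02; otherwise UNASSIGNED). Form IV
copies never count toward CO₂-fixation eligibility, and archaeal form
III copies count only when PRK is present (their PRK-lacking
configuration marks the pentose bisphosphate pathway instead). rbcS
co-occurrence and operon-scale colocalization (±5 loci) are reported per
copy. Desk-scale phylogenetics — greedy clustering at 80% identity,
gap-threshold (0.8) alignment trimming, and neighbor-joining on
1 − identity distances — supports the form panel; alignments can be
exported for external maximum-likelihood tools.

**Trait rules.** Marker presence maps to predicted electron donors and
acceptors: uptake hydrogenases ([NiFe] groups 1, 2a–2e, 4h, 4i; [FeFe]
groups A2, A3) for H₂; the sox system (soxABXYZ complete, or lacking
only soxB) and sqr for sulfur species; A-family heme–copper oxidases
(coxAB or cyoABCD) for low-affinity aerobic O₂ use versus C-family
(ccoNO) and cytochrome *bd* (cydAB) oxidases for microaerophilic O₂
use; narG+narH for nitrate respiration; dsrAB for sulfur-species
reduction; and pufL+pufM for type-II anoxygenic phototrophy (always
flagged with the caveat that CBB genes in phototrophs do not guarantee
autotrophy). Donors × acceptors give the predicted
chemolithoautotrophic growth modes for CBB-eligible genomes.

**Reporting.** Trait profiles joined with strain metadata (taxonomy,
literature evidence of autotrophic growth, isolation environment)
aggregate into per-order/per-phylum count matrices and form-stratified
environment breakdowns, with column-wise conservation checked on every
table.

**Synthetic benchmarks.** A generator emits ground-truthed proteomes —
marker genes mutated to controlled identities, rbcL copies derived from
panel references, rbcS at chosen locus offsets, residue-shuffled decoys
— so every stage is testable for exact recovery without downloads. The
bundled seed catalog and reference panel are deterministic synthetic
stand-ins emulating the divergence structure of the real families (see
`docs/methods.md`).

## Worked example

```python
from rubiscan import (FormLabel, GenomeTruth, SyntheticSpec, analyze_genome,
                      default_catalog, default_panel, generate)

catalog, panel = default_catalog(), default_panel()
truth = GenomeTruth(genome_id="knallgas", forms=(FormLabel.IE,),
                    hydrogenase_groups=("NiFe:2a",),
                    aerobic_genes=("coxA", "coxB"), nitrate_reduction=True)
genomes, _, _ = generate(SyntheticSpec(genomes=(truth,), rng_seed=5), catalog, panel)
analysis = analyze_genome(genomes[0], catalog, panel)
for mode in analysis.growth_modes:
    print(mode.donor, "->", mode.acceptor, mode.mode)
```

prints

```
H2 -> O2_aerobic chemolithoautotrophy
H2 -> nitrate chemolithoautotrophy
```

i.e. a genome with a complete CBB module, form IE RbcL, an uptake
[NiFe]-hydrogenase, an A-family oxidase and narG/narH is predicted to
grow as a hydrogen-oxidizing chemolithoautotroph with either oxygen
(aerobically) or nitrate (anaerobically) as the electron acceptor — the
configuration typical of *Actinomycetota* CBB candidates.

The `examples/` directory holds one short narrative script per
capability (marker detection, form classification, growth-mode
prediction, summary tables, synthetic benchmarking); each prints the
numbers it computes and says what they mean.

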
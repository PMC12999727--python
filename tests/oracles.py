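"""Independent brute-force oracles used only by the tests.

These deliberately re-derive, with plain dynamic programming and
explicit loops, the quantities the package computes through library
code, so that implementation and check never share a code path beyond
the BLOSUM62 score table itself.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11  # cost of the first gapped residue
GAP_EXTEND = 1  # cost of each further gapped residue

NEG = float(-1e18)


def _score(a: str, b: str) -> float:
    return float(_BLOSUM[a][b])


def nw_align(a: str, b: str) -> tuple[float, float]:
    """Global affine-gap alignment by explicit Gotoh DP with traceback.

    Returns ``(score, identity)`` where identity = identical pairs /
    alignment columns and ``X`` never counts as identical.  Traceback
    prefers substitution over gaps, so for pairs whose optimum is
    gapless the reported identity is exact and unique.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (a residue unpaired)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(GAP_OPEN + (i - 1) * GAP_EXTEND)
    for j in range(1, m + 1):
        Iy[0, j] = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + _score(a[i - 1], b[j - 1])
            Ix[i, j] = max(M[i - 1, j] - GAP_OPEN, Ix[i - 1, j] - GAP_EXTEND, Iy[i - 1, j] - GAP_OPEN)
            Iy[i, j] = max(M[i, j - 1] - GAP_OPEN, Iy[i, j - 1] - GAP_EXTEND, Ix[i, j - 1] - GAP_OPEN)
    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback, preferring M, then Ix, then Iy on ties
    i, j = n, m
    if M[i, j] >= max(Ix[i, j], Iy[i, j]):
        state = "M"
    elif Ix[i, j] >= Iy[i, j]:
        state = "X"
    else:
        state = "Y"
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == "M":
            if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                matches += 1
            prev = M[i, j] - _score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - prev) < 1e-9:
                state = "M"
            elif abs(Ix[i, j] - prev) < 1e-9:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            value = Ix[i, j]
            i -= 1
            if abs(M[i, j] - GAP_OPEN - value) < 1e-9:
                state = "M"
            elif abs(Ix[i, j] - GAP_EXTEND - value) < 1e-9:
                state = "X"
            else:
                state = "Y"
        else:
            value = Iy[i, j]
            j -= 1
            if abs(M[i, j] - GAP_OPEN - value) < 1e-9:
                state = "M"
            elif abs(Iy[i, j] - GAP_EXTEND - value) < 1e-9:
                state = "Y"
            else:
                state = "X"
    return float(score), matches / columns


def greedy_cluster(seqs, threshold, identity_fn):
    """Reference greedy clustering: longest-first, first matching representative."""
    ordered = sorted(seqs, key=lambda item: (-len(item[1]), item[0]))
    reps: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for seq_id, seq in ordered:
        for rep_id, rep_seq in reps:
            if identity_fn(seq, rep_seq) >= threshold:
                assignment[seq_id] = rep_id
                break
        else:
            reps.append((seq_id, seq))
            assignment[seq_id] = seq_id
    return assignment


def cbb_complete_bruteforce(markers: set[str]) -> bool:
    """Direct boolean transcription of the four-step module criterion."""
    return (
        "K00855" in markers
        and "K01601" in markers
        and "K00927" in markers
        and ("K05298" in markers or "K00150" in markers or "K00134" in markers)
    )


def traits_bruteforce(markers: set[str]) -> dict:
    """Independently coded donor/acceptor rule evaluation over marker sets."""
    has = markers.__contains__
    if has("soxA") and has("soxB") and has("soxX") and has("soxY") and has("soxZ"):
        sulfur = "complete_sox"
    elif has("soxA") and has("soxX") and has("soxY") and has("soxZ") and not has("soxB"):
        sulfur = "partial_sox_lacking_soxB"
    elif has("sqr"):
        sulfur = "sqr_only"
    else:
        sulfur = "none"
    return {
        "sulfur_oxidation": sulfur,
        "oxygen_aerobic_lowaff": (has("coxA") and has("coxB"))
        or (has("cyoA") and has("cyoB") and has("cyoC") and has("cyoD")),
        "oxygen_microaerophilic_highaff": (has("ccoN") and has("ccoO")) or (has("cydA") and has("cydB")),
        "nitrate_reduction": has("narG") and has("narH"),
        "sulfur_reduction": has("dsrA") and has("dsrB"),
        "photosystem_ii": has("pufL") and has("pufM"),
    }
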
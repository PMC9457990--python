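"""Standalone free-energy evaluation of a given secondary structure.

This module scores an arbitrary (sequence, structure) pair by summing
loop contributions — hairpins, stacks, bulges, internal loops,
multibranch loops and the exterior loop — under the same model the
dynamic-programming folder optimises. It is deliberately independent of
the folder's search code: the folder's traceback is re-scored against
it in the test-suite, and the exhaustive enumerator below uses it as
the brute-force oracle for small sequences.

Indexing here is 0-based on the encoded sequence; public structures use
1-based pairs and are converted on entry.
"""
from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .energetics import INF, MAXLOOP, PAIR_TABLE, EnergyModel
from .sequences import NucleotideSequence
from .structure import MIN_HAIRPIN, SecondaryStructure, validate_watson_crick


def pair_type(s: np.ndarray, i: int, j: int) -> int:
    return int(PAIR_TABLE[s[i], s[j]])


def hairpin_energy(s: np.ndarray, bases: str, i: int, j: int, m: EnergyModel) -> float:
    size = j - i - 1
    pt = pair_type(s, i, j)
    if pt < 0 or size < MIN_HAIRPIN:
        return INF
    if size == 4:
        bonus = m.special_hairpins.get(bases[i : j + 1])
        if bonus is not None:
            return bonus
    if size <= 30:
        e = m.hairpin[size]
    else:
        e = m.hairpin[30] + m.lxc * np.log(size / 30.0)
    if size == 3:
        bonus = m.special_hairpins.get(bases[i : j + 1])
        if bonus is not None:
            return bonus
        return e + m.at_penalty(pt)
    return e + m.tstackh[pt, s[i + 1] + 1, s[j - 1] + 1]


def internal_energy(
    s: np.ndarray, i: int, j: int, k: int, l: int, m: EnergyModel
) -> float:
    """Energy of the two-sided loop between outer pair (i,j) and inner (k,l).

    Covers stacks (0x0), bulges (0xn) and internal loops (n1 x n2).
    """
    pt1 = pair_type(s, i, j)
    pt2 = pair_type(s, l, k)  # inner pair read on the reverse strand
    if pt1 < 0 or pt2 < 0:
        return INF
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 < 0 or n2 < 0:
        return INF
    size = n1 + n2
    if size == 0:
        return float(m.stack[pt1, pt2])
    if size > MAXLOOP:
        return INF
    if n1 == 0 or n2 == 0:  # bulge
        e = float(m.bulge[size])
        if size == 1:
            e += float(m.stack[pt1, pt2])
        else:
            e += m.at_penalty(pt1) + m.at_penalty(pair_type(s, k, l))
        return e
    e = float(m.internal[max(4, size)])
    e += min(m.ninio_max, m.ninio_per_asym * abs(n1 - n2))
    if min(n1, n2) >= 2 and max(n1, n2) >= 3:
        e += float(m.tstacki[pt1, s[i + 1] + 1, s[j - 1] + 1])
        e += float(m.tstacki[pt2, s[l + 1] + 1, s[k - 1] + 1])
    return e


def multi_branch_term(
    s: np.ndarray, k: int, l: int, m: EnergyModel, n: int
) -> float:
    """Contribution of one helix (k,l) seen from inside a multibranch loop."""
    pt = pair_type(s, k, l)
    e = m.ml_branch + m.at_penalty(pt)
    if m.use_dangles:
        e += float(m.mm_multi[pt, s[k - 1] + 1, s[l + 1] + 1])
    return e


def exterior_branch_term(s: np.ndarray, k: int, l: int, m: EnergyModel) -> float:
    """Contribution of one top-level helix (k,l) in the exterior loop."""
    pt = pair_type(s, k, l)
    e = m.at_penalty(pt)
    if m.use_dangles:
        x = s[k - 1] + 1 if k > 0 else 0
        y = s[l + 1] + 1 if l < len(s) - 1 else 0
        e += float(m.mm_ext[pt, x, y])
    return e


def multiloop_energy(
    s: np.ndarray, i: int, j: int, branches: Sequence[Tuple[int, int]], m: EnergyModel
) -> float:
    unpaired = (j - i - 1) - sum(l - k + 1 for k, l in branches)
    pt_rev = pair_type(s, j, i)
    e = m.ml_closing + m.ml_unpaired * unpaired
    e += m.ml_branch + m.at_penalty(pair_type(s, i, j))
    if m.use_dangles:
        e += float(m.mm_multi[pt_rev, s[j - 1] + 1, s[i + 1] + 1])
    for k, l in branches:
        e += multi_branch_term(s, k, l, m, len(s))
    return e


def score_structure(
    seq: NucleotideSequence, structure: SecondaryStructure, model: EnergyModel
) -> float:
    """Total free energy (kcal/mol) of ``structure`` on ``seq``.

    The open chain scores exactly 0.
    """
    if structure.length != len(seq):
        raise ValueError("structure length does not match sequence")
    validate_watson_crick(seq.bases, structure)
    s = seq.encode()
    bases = seq.bases
    pairs0 = sorted((i - 1, j - 1) for i, j in structure.pairs)
    partner = {i: j for i, j in pairs0}

    def children(i: int, j: int) -> List[Tuple[int, int]]:
        out = []
        k = i + 1
        while k < j:
            if k in partner:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    total = 0.0
    for i, j in pairs0:
        kids = children(i, j)
        if not kids:
            total += hairpin_energy(s, bases, i, j, model)
        elif len(kids) == 1:
            (k, l) = kids[0]
            total += internal_energy(s, i, j, k, l, model)
        else:
            total += multiloop_energy(s, i, j, kids, model)

    # exterior loop: top-level branches
    top = []
    k = 0
    n = len(s)
    while k < n:
        if k in partner:
            top.append((k, partner[k]))
            k = partner[k] + 1
        else:
            k += 1
    for k, l in top:
        total += exterior_branch_term(s, k, l, model)
    return float(total)


MAX_ENUMERATION_LENGTH = 14


def enumerate_structures(
    seq: NucleotideSequence, model: EnergyModel
) -> List[Tuple[SecondaryStructure, float]]:
    """Every legal pseudoknot-free structure of a short sequence, scored.

    Exhaustive by construction (Watson-Crick pairs, minimum hairpin
    loop of 3), including the open chain at 0.0; the guard on sequence
    length keeps the combinatorics honest. This is the brute-force
    oracle the MFE folder is tested against.
    """
    n = len(seq)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"enumeration limited to {MAX_ENUMERATION_LENGTH} nt (got {n})"
        )
    s = seq.encode()

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def structures(i: int, j: int) -> Tuple[Tuple[Tuple[int, int], ...], ...]:
        """All pair-sets over closed interval [i, j]."""
        if j - i < MIN_HAIRPIN + 1:
            return ((),)
        out = list(structures(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if PAIR_TABLE[s[i], s[k]] < 0:
                continue
            for inner in structures(i + 1, k - 1):
                for rest in structures(k + 1, j):
                    out.append(((i, k),) + inner + rest)
        return tuple(out)

    results = []
    for pairset in structures(0, n - 1):
        st = SecondaryStructure(n, frozenset((i + 1, j + 1) for i, j in pairset))
        results.append((st, score_structure(seq, st, model)))
    return results
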
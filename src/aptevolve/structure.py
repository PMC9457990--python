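"""Secondary-structure representation and dot-bracket round-tripping.

Structures are sets of 1-based (i, j) base pairs, i < j, restricted to
non-crossing (pseudoknot-free) Watson-Crick pairings with a minimum
hairpin loop of three unpaired bases. Wobble pairs are excluded: this is
a DNA model.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple

MIN_HAIRPIN = 3

# Watson-Crick partners
WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings or illegal pair sets."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over a sequence of given length."""

    length: int
    pairs: FrozenSet[Tuple[int, int]]

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i},{j}) out of bounds for length {self.length}")
            if j - i - 1 < MIN_HAIRPIN:
                raise StructureError(f"pair ({i},{j}) violates minimum hairpin loop")
            if i in seen or j in seen:
                raise StructureError(f"index in more than one pair near ({i},{j})")
            seen.add(i)
            seen.add(j)
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i1, j1 = plist[a]
            for b in range(a + 1, len(plist)):
                i2, j2 = plist[b]
                if i1 < i2 < j1 < j2:
                    raise StructureError(
                        f"crossing pairs ({i1},{j1}) and ({i2},{j2}) (pseudoknot)"
                    )

    @property
    def dot_bracket(self) -> str:
        return to_dot_bracket(self)

    def is_open_chain(self) -> bool:
        return not self.pairs


def open_chain(length: int) -> SecondaryStructure:
    return SecondaryStructure(length, frozenset())


def to_dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def parse_dot_bracket(db: str) -> SecondaryStructure:
    """Parse '(', ')', '.' notation into a pair set (1-based indices)."""
    stack = []
    pairs = set()
    for pos, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(len(db), frozenset(pairs))


def validate_watson_crick(bases: str, structure: SecondaryStructure) -> None:
    """Reject structures whose pairs are not Watson-Crick on this sequence."""
    for i, j in structure.pairs:
        if (bases[i - 1], bases[j - 1]) not in WC:
            raise StructureError(
                f"pair ({i},{j}) = {bases[i-1]}-{bases[j-1]} is not Watson-Crick"
            )


def pairs_from_indices(pairs: Iterable[Tuple[int, int]], length: int) -> SecondaryStructure:
    return SecondaryStructure(length, frozenset((min(i, j), max(i, j)) for i, j in pairs))
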
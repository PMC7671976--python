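"""Point mutations and variants in wild-type/position/mutant notation.

A variant is a set of up to three point mutations at pairwise-distinct
residue positions, written the way the enzyme-engineering literature writes
them: ``C47V/G204A/S239D`` means Cys47->Val, Gly204->Ala and Ser239->Asp on
the same molecule. The empty mutation set is the wild type, written ``WT``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

WT_LABEL = "WT"

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single amino-acid substitution at one residue position."""

    position: int
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AA_INDEX or self.mut not in AA_INDEX:
            raise ValueError(f"unknown amino acid in mutation {self.wt}{self.position}{self.mut}")
        if self.wt == self.mut:
            raise ValueError(f"mutation {self.wt}{self.position}{self.mut} does not change the residue")
        if self.position < 1:
            raise ValueError("residue positions are 1-based")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, text: str) -> "PointMutation":
        m = _MUTATION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse point mutation {text!r}")
        return cls(position=int(m.group(2)), wt=m.group(1), mut=m.group(3))


@dataclass(frozen=True)
class Variant:
    """An enzyme variant: 0-3 point mutations at distinct positions.

    The canonical string form sorts mutations by ascending position and
    joins them with "/"; the wild type is "WT". Variants hash and compare
    by their canonical form, so they can index DataFrames and kernel
    matrices directly.
    """

    mutations: tuple[PointMutation, ...]

    def __init__(self, mutations: Iterable[PointMutation] = ()):
        muts = tuple(sorted(mutations, key=lambda m: m.position))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValueError(f"variant has repeated positions: {positions}")
        object.__setattr__(self, "mutations", muts)

    def __str__(self) -> str:
        if not self.mutations:
            return WT_LABEL
        return "/".join(str(m) for m in self.mutations)

    def __iter__(self) -> Iterator[PointMutation]:
        return iter(self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.mutations)

    @property
    def is_wild_type(self) -> bool:
        return not self.mutations

    @classmethod
    def parse(cls, text: str) -> "Variant":
        text = text.strip()
        if not text or text.upper() == WT_LABEL:
            return cls(())
        return cls(PointMutation.parse(tok) for tok in text.split("/"))


WILD_TYPE = Variant(())


def check_duplicate_free(variants: Iterable[Variant]) -> list[str]:
    """Canonical strings of ``variants``; raises if any string repeats."""
    names = [str(v) for v in variants]
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate variant in set: {dup}")
    return names
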
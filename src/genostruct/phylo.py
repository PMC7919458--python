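"""Species tree for the four-taxon-plus-outgroup design, and Dollo polarization.

The fixed topology mirrors the *melanogaster* species complex: three ingroup
taxa (the *simulans* complex trio) joined by a stem branch, a reference taxon
(*D. melanogaster* analog) as their sister, and a single outgroup used to
polarize derived states.  Branch names double as event labels throughout the
package: each ingroup terminal is named after its taxon, ``stem`` is the
internal branch ancestral to the trio, the reference terminal is named after
the reference taxon, and ``root`` is the edge subtending reference + trio
(i.e. the mel-complex stem, on which the outgroup is the only non-descendant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DERIVED = "derived"
ANCESTRAL = "ancestral"
MISSING = "missing"


@dataclass(frozen=True)
class Phylogeny:
    """Fixed 4-taxon + outgroup topology with per-branch durations (Myr)."""

    ingroup: tuple[str, str, str] = ("sim", "mau", "sec")
    reference: str = "mel"
    outgroup: str = "yak"
    #: Myr per branch; keys are branch names (see module docstring).
    durations: dict[str, float] = field(
        default_factory=lambda: {
            "sim": 0.25,
            "mau": 0.25,
            "sec": 0.25,
            "stem": 2.5,
            "mel": 2.75,
            "root": 3.25,
        }
    )

    def __post_init__(self) -> None:
        names = set(self.ingroup) | {self.reference, self.outgroup}
        if len(names) != 5:
            raise ValueError("taxa must be five distinct names")
        missing = set(self.branches) - set(self.durations)
        if missing:
            raise ValueError(f"missing branch durations: {sorted(missing)}")
        if any(d <= 0 for d in self.durations.values()):
            raise ValueError("branch durations must be > 0")

    @property
    def taxa(self) -> tuple[str, ...]:
        """All taxa in canonical order: ingroup trio, reference, outgroup."""
        return (*self.ingroup, self.reference, self.outgroup)

    @property
    def branches(self) -> tuple[str, ...]:
        return (*self.ingroup, "stem", self.reference, "root")

    def descendants(self, branch: str) -> frozenset[str]:
        """Taxa below a branch (the taxa that inherit an event on it)."""
        if branch in self.ingroup:
            return frozenset({branch})
        if branch == "stem":
            return frozenset(self.ingroup)
        if branch == self.reference:
            return frozenset({self.reference})
        if branch == "root":
            return frozenset(self.ingroup) | {self.reference}
        raise KeyError(branch)

    def path(self, taxon: str) -> tuple[str, ...]:
        """Root-to-tip branch path for a taxon (empty for the outgroup)."""
        if taxon in self.ingroup:
            return ("root", "stem", taxon)
        if taxon == self.reference:
            return ("root", taxon)
        if taxon == self.outgroup:
            return ()
        raise KeyError(taxon)


def dollo_assign(states: dict[str, str], phylogeny: Phylogeny) -> str | None:
    """Assign a binary character to the unique branch allowing a single origin.

    ``states`` maps each taxon (outgroup included) to ``derived``,
    ``ancestral`` or ``missing``.  A branch is consistent when all non-missing
    taxa below it share one state, all non-missing taxa outside share the
    other, and the two states differ.  Returns the branch name when exactly
    one branch is consistent, else ``None`` (ambiguous or conflicting
    pattern).  Rows with no informative contrast return ``None``.
    """
    informative = {t: s for t, s in states.items() if s != MISSING}
    if len(set(informative.values())) < 2:
        return None
    hits = []
    for branch in phylogeny.branches:
        desc = phylogeny.descendants(branch)
        inside = {s for t, s in informative.items() if t in desc}
        outside = {s for t, s in informative.items() if t not in desc}
        if len(inside) == 1 and len(outside) == 1 and inside != outside:
            hits.append(branch)
    return hits[0] if len(hits) == 1 else None
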
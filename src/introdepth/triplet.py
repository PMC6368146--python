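"""The three rooted resolutions of a focal species triplet (A, B, C).

Throughout the package the four roles are fixed strings: ``A``, ``B``, ``C``
are the ingroup triplet and ``O`` is the outgroup. A gene tree over the four
roles resolves the triplet as one of three topologies (or not at all, when
the relevant node is a polytomy).
"""

from __future__ import annotations

import enum

ROLES = ("A", "B", "C", "O")
INGROUP = ("A", "B", "C")


class TripletTopology(enum.Enum):
    """Rooted resolution of the triplet {A, B, C} with outgroup O."""

    AB_C = "AB|C"
    AC_B = "AC|B"
    BC_A = "BC|A"
    UNRESOLVED = "UNRESOLVED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def cherry(self) -> tuple[str, str]:
        """The sister pair, e.g. ``("A", "B")`` for AB|C."""
        if self is TripletTopology.UNRESOLVED:
            raise ValueError("UNRESOLVED topology has no cherry pair")
        return tuple(self.value.split("|")[0])  # type: ignore[return-value]

    @property
    def odd_taxon(self) -> str:
        """The ingroup taxon outside the cherry."""
        if self is TripletTopology.UNRESOLVED:
            raise ValueError("UNRESOLVED topology has no odd taxon")
        return self.value.split("|")[1]

    @classmethod
    def from_cherry(cls, x: str, y: str) -> "TripletTopology":
        """Topology whose cherry is the unordered pair {x, y}."""
        pair = frozenset((x, y))
        for topo in (cls.AB_C, cls.AC_B, cls.BC_A):
            if frozenset(topo.cherry) == pair:
                return topo
        raise ValueError(f"not a pair from {INGROUP}: {x!r}, {y!r}")

    @classmethod
    def from_string(cls, s: str) -> "TripletTopology":
        for topo in cls:
            if topo.value == s:
                return topo
        raise ValueError(f"unknown topology string {s!r}")


RESOLVED = (TripletTopology.AB_C, TripletTopology.AC_B, TripletTopology.BC_A)
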
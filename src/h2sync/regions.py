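"""The seven anatomical region roles and their groupings.

The analysis operates on bipolar SEEG signals assigned to at most seven
regions of interest: three mesial temporal structures (amygdala A,
hippocampus Hip, entorhinal cortex EC), three neocortical temporal gyri
(superior STG, middle MTG, inferior ITG) and the thalamus (Th).
"""

from __future__ import annotations

from enum import Enum


class RegionGroup(Enum):
    MESIAL = "mesial"
    NEOCORTICAL = "neocortical"
    THALAMIC = "thalamic"


class RegionRole(Enum):
    """One of the seven regions of interest, in canonical order."""

    A = "A"
    Hip = "Hip"
    EC = "EC"
    STG = "STG"
    MTG = "MTG"
    ITG = "ITG"
    Th = "Th"

    @property
    def group(self) -> RegionGroup:
        if self in MESIAL_ROLES:
            return RegionGroup.MESIAL
        if self is RegionRole.Th:
            return RegionGroup.THALAMIC
        return RegionGroup.NEOCORTICAL

    def __str__(self) -> str:  # compact labels in tables and edge lists
        return self.value


ROLE_ORDER: tuple[RegionRole, ...] = (
    RegionRole.A,
    RegionRole.Hip,
    RegionRole.EC,
    RegionRole.STG,
    RegionRole.MTG,
    RegionRole.ITG,
    RegionRole.Th,
)

MESIAL_ROLES: frozenset[RegionRole] = frozenset(
    {RegionRole.A, RegionRole.Hip, RegionRole.EC}
)
NEOCORTICAL_ROLES: frozenset[RegionRole] = frozenset(
    {RegionRole.STG, RegionRole.MTG, RegionRole.ITG}
)


def role_pairs(roles: list[RegionRole]) -> list[tuple[RegionRole, RegionRole]]:
    """All unordered region pairs in canonical order."""
    ordered = [r for r in ROLE_ORDER if r in roles]
    return [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    ]
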
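"""Homogeneous temperature zones of India.

The IMD/IITM classification divides India into seven homogeneous
temperature zones. Each zone carries a fixed operational heat-wave
cutoff for daily maximum temperature: 40 °C over the plains, 37 °C
along the coasts, and 30 °C in the hilly regions. Zones are further
grouped into a northern block (Hilly, Northeast, Northwest, North
Central) and a southern block (Interior Peninsula, West Coast, East
Coast).
"""

from __future__ import annotations

import enum


class Zone(enum.Enum):
    """One of the seven homogeneous temperature zones."""

    HILLY = "Hilly"
    NORTHEAST = "Northeast"
    NORTHWEST = "Northwest"
    NORTH_CENTRAL = "NorthCentral"
    INTERIOR_PENINSULA = "InteriorPeninsula"
    WEST_COAST = "WestCoast"
    EAST_COAST = "EastCoast"

    @property
    def fixed_threshold(self) -> float:
        """Fixed zone cutoff for daily Tmax, in °C."""
        if self is Zone.HILLY:
            return 30.0
        if self in (Zone.WEST_COAST, Zone.EAST_COAST):
            return 37.0
        return 40.0

    @property
    def hemisphere_group(self) -> str:
        """'north' or 'south' block of the seven-zone classification."""
        if self in (Zone.HILLY, Zone.NORTHEAST, Zone.NORTHWEST, Zone.NORTH_CENTRAL):
            return "north"
        return "south"

    @classmethod
    def from_label(cls, label: str) -> "Zone":
        """Resolve a zone label, raising ``ValueError`` listing the allowed labels."""
        for z in cls:
            if z.value == label:
                return z
        allowed = ", ".join(z.value for z in cls)
        raise ValueError(f"unknown zone label {label!r}; allowed labels: {allowed}")


ZONE_LABELS = tuple(z.value for z in Zone)
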
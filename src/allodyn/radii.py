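"""Van der Waals radii (Bondi set) used for SASA and contact geometry.

Values in Å. Elements missing from the table fall back to a generic
heavy-atom radius; hydrogens get the Bondi hydrogen radius.
"""

from __future__ import annotations

BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_HEAVY_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    """Bondi radius for an element symbol (case-insensitive)."""
    return BONDI_RADII.get(element.strip().upper(), DEFAULT_HEAVY_RADIUS)
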
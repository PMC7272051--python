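"""Bundled element masses (amu, standard atomic weights)."""

from __future__ import annotations

import warnings

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

#: Mass assigned to elements absent from the table (carbon-like bead).
DEFAULT_MASS = 12.011


def element_mass(element: str) -> float:
    """Mass in amu for an element symbol; unknown symbols get a carbon-like
    default with a warning."""
    key = element.strip().upper()
    if key in ELEMENT_MASSES:
        return ELEMENT_MASSES[key]
    warnings.warn(
        f"element {element!r} not in bundled mass table; using {DEFAULT_MASS} amu",
        stacklevel=2,
    )
    return DEFAULT_MASS
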
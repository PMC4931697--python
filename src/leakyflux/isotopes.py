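"""Natural isotope abundances used for mass-interference correction.

Values are IUPAC/CIAAW representative terrestrial abundances (Meija et
al., Pure Appl. Chem. 88:293, 2016; Rosman & Taylor, Pure Appl. Chem.
70:217, 1998).  Each entry lists the fractional abundance of isotopes in
increasing mass-shift order relative to the lightest (index = extra
neutrons = extra nominal mass units).
"""

from __future__ import annotations

import numpy as np

# element -> abundance vector over mass shifts +0, +1, +2, ...
NATURAL_ABUNDANCE: dict[str, np.ndarray] = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0001]),
}

#: natural abundance of 13C, used for backbone carbons
P13C = float(NATURAL_ABUNDANCE["C"][1])


def element_distribution(element: str, count: int) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of `element` (self-convolution)."""
    try:
        base = NATURAL_ABUNDANCE[element]
    except KeyError:
        raise KeyError(f"unknown element symbol {element!r}") from None
    dist = np.array([1.0])
    for _ in range(count):
        dist = np.convolve(dist, base)
    return dist


def formula_distribution(formula: dict[str, int]) -> np.ndarray:
    """Mass-shift distribution of a chemical formula given as element counts."""
    dist = np.array([1.0])
    for element, count in sorted(formula.items()):
        if count < 0:
            raise ValueError(f"negative count for element {element}")
        if count:
            dist = np.convolve(dist, element_distribution(element, count))
    return dist
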
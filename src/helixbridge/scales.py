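"""Registered hydrophobicity scales.

Each scale maps the 20 canonical residues to a real value. Kyte–Doolittle
is the default (positive = hydrophobic). The Wimley–White interface scale
is a transfer free energy, so its sign convention is inverted relative to
the other two (negative = favourable partitioning into the membrane
interface); lagged correlation is invariant to affine rescaling but NOT to
sign, so scans using different scales should not be mixed in one consensus.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownScaleError
from .families import AMINO_ACIDS

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

EISENBERG_CONSENSUS = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Water -> POPC-interface transfer free energy (kcal/mol); lower = more
# readily buried at the interface.
WIMLEY_WHITE_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

_SCALES: dict[str, dict[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG_CONSENSUS,
    "wimley-white-interface": WIMLEY_WHITE_INTERFACE,
}

DEFAULT_SCALE = "kyte-doolittle"


def registered_scales() -> list[str]:
    return sorted(_SCALES)


def register_scale(scale_id: str, values: dict[str, float]) -> None:
    """Register a user-supplied 20-value scale under ``scale_id``."""
    missing = set(AMINO_ACIDS) - set(values)
    if missing:
        raise ValueError(f"scale '{scale_id}' missing residues {sorted(missing)}")
    _SCALES[scale_id] = {aa: float(values[aa]) for aa in AMINO_ACIDS}


def scale_vector(scale_id: str) -> np.ndarray:
    """The scale as a length-20 vector in canonical residue order."""
    try:
        table = _SCALES[scale_id]
    except KeyError:
        raise UnknownScaleError(
            f"unknown scale '{scale_id}'; registered scales: {registered_scales()}"
        ) from None
    return np.array([table[aa] for aa in AMINO_ACIDS], dtype=np.float64)
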
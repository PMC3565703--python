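"""Per-column property tracks over transmembrane helix windows.

Three measures are supported: Shannon entropy in bits (conservation),
frequency-weighted mean hydrophobicity, and Baldwin-style variability
(number of distinct residue types above a frequency floor). A helical
moment diagnostic summarizes the periodicity of any track.

All tracks exclude gaps and unknowns from the frequency normalization.
Columns more than half gapped are flagged (``high_gap``) but still scored:
transmembrane windows are rarely gapped and dropping columns would break
the rectangular lag windows the scans rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyColumnError
from .families import AlignedFamily
from .scales import DEFAULT_SCALE, scale_vector

MAX_ENTROPY_BITS = math.log2(20)
HIGH_GAP_FRACTION = 0.5
DEFAULT_TWIST_DEG = 100.0  # ideal alpha-helix rotation per residue


@dataclass
class PropertyProfile:
    """A numeric per-column track for one helix window of one family."""

    family_id: str
    helix_id: str
    measure: str  # entropy | hydrophobicity | variability
    columns: np.ndarray  # 1-based alignment columns, strictly increasing
    values: np.ndarray
    scale_id: str | None = None
    tm_start_col: int = 0  # 1-based first column of the TM window proper
    tm_end_col: int = 0
    high_gap_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.columns) != len(self.values):
            raise ValueError("columns and values differ in length")
        if len(self.columns) and np.any(np.diff(self.columns) <= 0):
            raise ValueError("columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, col: int) -> float:
        idx = np.searchsorted(self.columns, col)
        if idx >= len(self.columns) or self.columns[idx] != col:
            raise KeyError(f"column {col} not in profile")
        return float(self.values[idx])

    def window_values(self, start_col: int, stop_col: int) -> np.ndarray:
        """Values for columns ``start_col..stop_col`` (1-based inclusive);
        NaN where the profile does not cover a column."""
        out = np.full(stop_col - start_col + 1, np.nan)
        lo, hi = self.columns[0], self.columns[-1]
        for i, col in enumerate(range(start_col, stop_col + 1)):
            if lo <= col <= hi:
                out[i] = self.values[col - lo]
        return out


def _window_columns(
    family: AlignedFamily, helix_id: str, pad: int
) -> tuple[np.ndarray, int, int]:
    region = family.region(helix_id)
    start = max(1, region.start_col - pad)
    stop = min(family.n_columns, region.end_col + pad)
    return np.arange(start, stop + 1), region.start_col, region.end_col


def column_frequencies(family: AlignedFamily, col: int) -> tuple[np.ndarray, float]:
    """Frequencies over the 20 residues plus gap fraction for one column."""
    return family.column_frequencies(col)


def shannon_entropy(freq: np.ndarray) -> float:
    """Shannon entropy in bits of a frequency vector (zeros ignored)."""
    nz = freq[freq > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropy_profile(
    family: AlignedFamily, helix_id: str, pad: int = 0
) -> PropertyProfile:
    """Per-column Shannon entropy (bits) over the helix window ± pad."""
    cols, tm_start, tm_end = _window_columns(family, helix_id, pad)
    freq = family.frequency_matrix()[cols - 1]
    if np.isnan(freq).any():
        empty = cols[np.isnan(freq).any(axis=1)]
        raise EmptyColumnError(
            f"{family.family_id}/{helix_id}: empty column(s) {empty.tolist()}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freq > 0, np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    values = -(freq * logf).sum(axis=1)
    return PropertyProfile(
        family_id=family.family_id,
        helix_id=helix_id,
        measure="entropy",
        columns=cols,
        values=values,
        tm_start_col=tm_start,
        tm_end_col=tm_end,
        high_gap_columns=_high_gap(family, cols),
    )


def hydrophobicity_profile(
    family: AlignedFamily,
    helix_id: str,
    pad: int = 0,
    scale_id: str = DEFAULT_SCALE,
) -> PropertyProfile:
    """Frequency-weighted mean hydrophobicity per column (gaps/X excluded)."""
    vec = scale_vector(scale_id)
    cols, tm_start, tm_end = _window_columns(family, helix_id, pad)
    freq = family.frequency_matrix()[cols - 1]
    if np.isnan(freq).any():
        empty = cols[np.isnan(freq).any(axis=1)]
        raise EmptyColumnError(
            f"{family.family_id}/{helix_id}: empty column(s) {empty.tolist()}"
        )
    return PropertyProfile(
        family_id=family.family_id,
        helix_id=helix_id,
        measure="hydrophobicity",
        columns=cols,
        values=freq @ vec,
        scale_id=scale_id,
        tm_start_col=tm_start,
        tm_end_col=tm_end,
        high_gap_columns=_high_gap(family, cols),
    )


def variability_profile(
    family: AlignedFamily,
    helix_id: str,
    min_freq: float = 0.0,
    pad: int = 0,
) -> PropertyProfile:
    """Count of distinct residue types with frequency > ``min_freq``.

    This is the Baldwin-style variability used to pick out lipid-facing
    stretches: buried positions admit few residue types, exposed ones many.
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError(f"min_freq must be in [0, 1), got {min_freq}")
    cols, tm_start, tm_end = _window_columns(family, helix_id, pad)
    freq = family.frequency_matrix()[cols - 1]
    if np.isnan(freq).any():
        empty = cols[np.isnan(freq).any(axis=1)]
        raise EmptyColumnError(
            f"{family.family_id}/{helix_id}: empty column(s) {empty.tolist()}"
        )
    values = (freq > min_freq).sum(axis=1).astype(np.float64)
    return PropertyProfile(
        family_id=family.family_id,
        helix_id=helix_id,
        measure="variability",
        columns=cols,
        values=values,
        tm_start_col=tm_start,
        tm_end_col=tm_end,
        high_gap_columns=_high_gap(family, cols),
    )


def _high_gap(family: AlignedFamily, cols: np.ndarray) -> tuple[int, ...]:
    gaps = family.gap_fractions()[cols - 1]
    return tuple(int(c) for c in cols[gaps > HIGH_GAP_FRACTION])


def helical_moment(
    profile: PropertyProfile, twist_deg: float = DEFAULT_TWIST_DEG
) -> tuple[float, float, bool]:
    """Vector sum of the track placed around a helical wheel.

    Residue i contributes its value at angle ``i * twist_deg``. Returns
    ``(magnitude, direction_deg, direction_defined)``; for a zero-magnitude
    moment the direction is reported as 0 with the flag cleared. With the
    ideal 100 deg twist a constant track over a full turn cancels, so a
    large moment signals one helix face carrying systematically different
    values — the inward/outward asymmetry the alignment method exploits.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    angles = np.deg2rad(np.arange(len(profile)) * twist_deg)
    x = float(np.sum(profile.values * np.cos(angles)))
    y = float(np.sum(profile.values * np.sin(angles)))
    magnitude = math.hypot(x, y)
    if magnitude < 1e-12:
        return 0.0, 0.0, False
    return magnitude, math.degrees(math.atan2(y, x)) % 360.0, True


def profiles_frame(profiles: list[PropertyProfile]):
    """Tidy table of profiles: family_id, helix_id, measure, column, value."""
    import pandas as pd

    rows = []
    for p in profiles:
        for col, val in zip(p.columns, p.values):
            rows.append(
                {
                    "family_id": p.family_id,
                    "helix_id": p.helix_id,
                    "measure": p.measure,
                    "column": int(col),
                    "value": float(val),
                }
            )
    return pd.DataFrame(rows)
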
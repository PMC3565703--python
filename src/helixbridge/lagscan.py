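"""Lagged scan scoring: the core of the alignment method.

For a pair of families and one helix, three per-lag traces are computed
over a grid of integer lags (default -8..+8, 17 lags):

* ``blosum`` — ungapped profile-alignment score: the expected BLOSUM62
  substitution score between the two families' column frequency profiles,
  summed over a sliding window the length of the first family's
  transmembrane region;
* ``entropy`` — Pearson correlation of the two families' per-column
  Shannon-entropy tracks over the same sliding window;
* ``hydrophobicity`` — the same for mean-hydrophobicity tracks.

Each trace is the mean of a forward scan (first family's window slid along
the second family) and a reverse scan (roles swapped, lag negated), then
min–max scaled to [0, 1]. The per-pairing consensus is the product of the
three scaled traces, which down-weights lags supported by only one
component.

Sign convention: at lag L the first family's window offset j is paired
with the second family's column at (TM start + j - L), so a NEGATIVE lag
displaces the second family's sequences to the LEFT. This matches the
displacement convention used throughout reporting and numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import LagGridMismatchError, MeasureMismatchError
from .families import AMINO_ACIDS, AlignedFamily
from .profiles import PropertyProfile

logger = logging.getLogger(__name__)

DEFAULT_PAD = 8
MIN_OVERLAP = 3
_NORM_TOL = 1e-8

_BLOSUM62_CACHE: np.ndarray | None = None


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 20x20 array in canonical residue order."""
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        mat = substitution_matrices.load("BLOSUM62")
        out = np.empty((20, 20), dtype=np.float64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                out[i, j] = mat[a, b]
        _BLOSUM62_CACHE = out
    return _BLOSUM62_CACHE


@dataclass
class LagScan:
    """Per-lag scores for one measure and one family pairing.

    ``raw`` holds the forward/reverse-averaged scores (NaN for lags whose
    window overlap fell below :data:`MIN_OVERLAP` columns); ``scaled`` the
    min–max rescaling of the finite raw values. ``flags`` maps a lag to
    descriptive markers such as ``truncated`` or ``zero_variance``.
    """

    pairing: tuple[str, str]
    helix_id: str
    measure: str  # blosum | entropy | hydrophobicity | consensus
    lags: np.ndarray
    raw: np.ndarray
    scaled: np.ndarray
    degenerate: bool = False
    flags: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.scaled = np.asarray(self.scaled, dtype=np.float64)
        if not (len(self.lags) == len(self.raw) == len(self.scaled)):
            raise ValueError("lags, raw and scaled must have equal length")

    def raw_at(self, lag: int) -> float:
        return float(self.raw[self._index(lag)])

    def scaled_at(self, lag: int) -> float:
        return float(self.scaled[self._index(lag)])

    def _index(self, lag: int) -> int:
        hits = np.flatnonzero(self.lags == lag)
        if not len(hits):
            raise KeyError(f"lag {lag} not on grid {self.lags.tolist()}")
        return int(hits[0])

    @property
    def argmax_lag(self) -> int:
        """Lag with the highest scaled value (NaNs ignored)."""
        finite = np.flatnonzero(np.isfinite(self.scaled))
        if not len(finite):
            raise ValueError("scan has no finite values")
        return int(self.lags[finite[np.argmax(self.scaled[finite])]])


def enumerate_lags(pad: int) -> np.ndarray:
    """The symmetric lag grid -pad..+pad (2*pad + 1 lags)."""
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    return np.arange(-pad, pad + 1, dtype=np.int64)


def profile_pair_score(
    freq_a: np.ndarray, freq_b: np.ndarray, matrix: np.ndarray | None = None
) -> float:
    """Expected substitution score between two column frequency profiles.

    sum_ab f_A(a) f_B(b) M(a, b); both vectors must be normalized.
    """
    freq_a = np.asarray(freq_a, dtype=np.float64)
    freq_b = np.asarray(freq_b, dtype=np.float64)
    for name, f in (("freq_a", freq_a), ("freq_b", freq_b)):
        if abs(f.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} not normalized (sum {f.sum():.6g})")
    if matrix is None:
        matrix = blosum62_matrix()
    return float(freq_a @ matrix @ freq_b)


def unit_scale(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min–max scale finite values onto [0, 1].

    Returns (scaled, degenerate); a flat trace maps to all zeros with the
    degenerate flag set. NaNs pass through untouched.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("cannot scale an empty trace")
    finite = np.isfinite(raw)
    if not finite.any():
        return np.full_like(raw, np.nan), True
    lo, hi = raw[finite].min(), raw[finite].max()
    if hi == lo:
        scaled = np.where(finite, 0.0, np.nan)
        return scaled, True
    return (raw - lo) / (hi - lo), False


def _directional_blosum(
    fam_x: AlignedFamily, fam_y: AlignedFamily, helix_id: str, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-direction profile-alignment scores.

    Slides fam_x's TM window along fam_y: at lag L, window offset j pairs
    with fam_y column (TM start + j - L). Returns (scores, overlaps); a
    score is NaN when fewer than MIN_OVERLAP column pairs survive clipping.
    """
    rx = fam_x.region(helix_id)
    ry = fam_y.region(helix_id)
    fx = fam_x.frequency_matrix()[rx.start_idx : rx.stop_idx]  # (Wx, 20)
    fy = fam_y.frequency_matrix()  # (Ny, 20)
    cross = fx @ blosum62_matrix() @ fy.T  # (Wx, Ny); NaN vs empty columns
    wx = rx.length
    scores = np.full(len(lags), np.nan)
    overlaps = np.zeros(len(lags), dtype=np.int64)
    for k, lag in enumerate(lags):
        j = np.arange(wx)
        ycols = ry.start_idx + j - int(lag)
        ok = (ycols >= 0) & (ycols < fam_y.n_columns)
        vals = cross[j[ok], ycols[ok]]
        vals = vals[np.isfinite(vals)]
        overlaps[k] = len(vals)
        if len(vals) >= MIN_OVERLAP:
            scores[k] = vals.sum()
    return scores, overlaps


def blosum_lag_scan(
    fam_x: AlignedFamily,
    fam_y: AlignedFamily,
    helix_id: str,
    pad: int = DEFAULT_PAD,
) -> LagScan:
    """Forward/reverse-averaged BLOSUM62 profile-alignment scan.

    raw(L) = mean(forward(L), reverse with roles swapped at -L), which
    makes the scan swap-symmetric: scan(x, y) at L equals scan(y, x) at -L.
    """
    lags = enumerate_lags(pad)
    fwd, n_fwd = _directional_blosum(fam_x, fam_y, helix_id, lags)
    rev, n_rev = _directional_blosum(fam_y, fam_x, helix_id, -lags)
    return _assemble_scan(
        (fam_x.family_id, fam_y.family_id),
        helix_id,
        "blosum",
        lags,
        fwd,
        rev,
        full_fwd=fam_x.region(helix_id).length,
        full_rev=fam_y.region(helix_id).length,
        n_fwd=n_fwd,
        n_rev=n_rev,
    )


def _directional_correlation(
    prof_x: PropertyProfile, prof_y: PropertyProfile, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    """Pearson correlation of prof_x's TM window against lagged prof_y."""
    wx = prof_x.tm_end_col - prof_x.tm_start_col + 1
    vx_full = prof_x.window_values(prof_x.tm_start_col, prof_x.tm_end_col)
    scores = np.full(len(lags), np.nan)
    overlaps = np.zeros(len(lags), dtype=np.int64)
    flat = [False] * len(lags)
    for k, lag in enumerate(lags):
        start = prof_y.tm_start_col - int(lag)
        vy = prof_y.window_values(start, start + wx - 1)
        ok = np.isfinite(vx_full) & np.isfinite(vy)
        overlaps[k] = int(ok.sum())
        if overlaps[k] < MIN_OVERLAP:
            continue
        a, b = vx_full[ok], vy[ok]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            # zero-variance window: correlation undefined, scored 0
            scores[k] = 0.0
            flat[k] = True
        else:
            scores[k] = float(np.corrcoef(a, b)[0, 1])
    return scores, overlaps, flat


def property_lag_scan(
    prof_x: PropertyProfile, prof_y: PropertyProfile, pad: int = DEFAULT_PAD
) -> LagScan:
    """Forward/reverse-averaged lagged correlation of two property tracks."""
    if prof_x.measure != prof_y.measure:
        raise MeasureMismatchError(
            f"measure mismatch: {prof_x.measure} vs {prof_y.measure}"
        )
    lags = enumerate_lags(pad)
    fwd, n_fwd, flat_f = _directional_correlation(prof_x, prof_y, lags)
    rev, n_rev, flat_r = _directional_correlation(prof_y, prof_x, -lags)
    scan = _assemble_scan(
        (prof_x.family_id, prof_y.family_id),
        prof_x.helix_id,
        prof_x.measure,
        lags,
        fwd,
        rev,
        full_fwd=prof_x.tm_end_col - prof_x.tm_start_col + 1,
        full_rev=prof_y.tm_end_col - prof_y.tm_start_col + 1,
        n_fwd=n_fwd,
        n_rev=n_rev,
    )
    for k, lag in enumerate(lags):
        if flat_f[k] or flat_r[k]:
            scan.flags[int(lag)] = scan.flags.get(int(lag), ()) + ("zero_variance",)
    return scan


def _assemble_scan(
    pairing: tuple[str, str],
    helix_id: str,
    measure: str,
    lags: np.ndarray,
    fwd: np.ndarray,
    rev: np.ndarray,
    full_fwd: int,
    full_rev: int,
    n_fwd: np.ndarray,
    n_rev: np.ndarray,
) -> LagScan:
    both = np.stack([fwd, rev])
    with np.errstate(invalid="ignore"):
        raw = np.nanmean(both, axis=0)
    scaled, degenerate = unit_scale(raw)
    flags: dict[int, tuple[str, ...]] = {}
    for k, lag in enumerate(lags):
        marks: list[str] = []
        if not np.isfinite(raw[k]):
            marks.append("missing")
            logger.info(
                "%s/%s %s: lag %d dropped (overlap below %d columns)",
                "-".join(pairing), helix_id, measure, lag, MIN_OVERLAP,
            )
        elif n_fwd[k] < full_fwd or n_rev[k] < full_rev:
            marks.append("truncated")
        if marks:
            flags[int(lag)] = tuple(marks)
    return LagScan(
        pairing=pairing,
        helix_id=helix_id,
        measure=measure,
        lags=lags,
        raw=raw,
        scaled=scaled,
        degenerate=degenerate,
        flags=flags,
    )


def consensus_scan(
    blosum: LagScan, entropy: LagScan, hydro: LagScan
) -> LagScan:
    """Per-lag product of the three scaled component traces.

    The product reinforces lags supported by every component and
    down-weights lags supported by a single one; it is not re-scaled, so
    each consensus value stays within (0, 1) and never exceeds any
    component's scaled value at the same lag.
    """
    components = (blosum, entropy, hydro)
    ref = components[0]
    for scan in components[1:]:
        if (
            scan.pairing != ref.pairing
            or scan.helix_id != ref.helix_id
            or not np.array_equal(scan.lags, ref.lags)
        ):
            raise LagGridMismatchError(
                "consensus components must share pairing, helix and lag grid"
            )
    product = components[0].scaled * components[1].scaled * components[2].scaled
    finite = np.isfinite(product)
    degenerate = bool(not finite.any() or np.ptp(product[finite]) == 0)
    flags: dict[int, tuple[str, ...]] = {}
    for scan in components:
        for lag, marks in scan.flags.items():
            flags[lag] = tuple(dict.fromkeys(flags.get(lag, ()) + marks))
    return LagScan(
        pairing=ref.pairing,
        helix_id=ref.helix_id,
        measure="consensus",
        lags=ref.lags.copy(),
        raw=product.copy(),
        scaled=product,
        degenerate=degenerate,
        flags=flags,
    )


def scans_frame(scans: list[LagScan]):
    """Tidy per-lag table: pairing, helix, measure, lag, raw, scaled, flags."""
    import pandas as pd

    rows = []
    for s in scans:
        for lag, raw, scaled in zip(s.lags, s.raw, s.scaled):
            rows.append(
                {
                    "pairing": "-".join(s.pairing),
                    "helix_id": s.helix_id,
                    "measure": s.measure,
                    "lag": int(lag),
                    "raw": float(raw),
                    "scaled": float(scaled),
                    "flags": ";".join(s.flags.get(int(lag), ())),
                }
            )
    return pd.DataFrame(rows)
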
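"""Statistical validation of a proposed alignment.

A proposed shift is supported when it brings the two families'
group-conserved residues (positions conserved as a residue class, e.g.
small residues A/G/S/C) into register more often than chance. The null
model places an equal number of positions uniformly at random within the
overlapping window; its upper tail is hypergeometric in closed form, and a
Monte-Carlo engine reproduces it (and admits non-uniform placement
weights). The reported p-value is the larger of the two one-sided values
obtained by randomizing either family's positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .errors import NoOverlapError
from .families import AMINO_ACIDS, AlignedFamily

MIN_MC_REPLICATES = 100
DEFAULT_MC_REPLICATES = 10_000
DEFAULT_MIN_GROUP_FREQ = 0.8

#: Named partition of the 20 residues into physicochemical classes; the
#: small-residue group drives the group-conserved analysis.
DEFAULT_RESIDUE_GROUPS: dict[str, frozenset[str]] = {
    "small": frozenset("AGSC"),
    "hydrophobic": frozenset("ILVMF"),
    "aromatic": frozenset("WYH"),
    "positive": frozenset("KR"),
    "negative": frozenset("DE"),
    "polar": frozenset("NQT"),
    "proline": frozenset("P"),
}


@dataclass(frozen=True)
class GroupConservedSet:
    """Group-conserved positions within one family's helix window.

    Positions are 1-based offsets from the transmembrane window start.
    """

    family_id: str
    helix_id: str
    positions: frozenset[int]
    window_length: int

    def __post_init__(self) -> None:
        bad = [p for p in self.positions if not 1 <= p <= self.window_length]
        if bad:
            raise ValueError(
                f"{self.family_id}/{self.helix_id}: positions {sorted(bad)} outside "
                f"[1, {self.window_length}]"
            )


@dataclass
class OverlapTest:
    """Observed aligned group-conserved count with exact and MC p-values."""

    helix_id: str
    shift: int
    observed: int
    overlap_length: int
    n_a: int
    n_b: int
    p_exact: float
    p_mc_randomize_a: float
    p_mc_randomize_b: float
    mc_replicates: int
    seed: int

    @property
    def reported_p(self) -> float:
        """The larger of the two one-sided randomization directions."""
        return max(self.p_mc_randomize_a, self.p_mc_randomize_b)


def _overlap_range(
    set_a: GroupConservedSet, set_b: GroupConservedSet, shift: int
) -> tuple[int, int]:
    """First-family offsets i with both i and i - shift inside a window."""
    lo = max(1, 1 + shift)
    hi = min(set_a.window_length, set_b.window_length + shift)
    if hi < lo:
        raise NoOverlapError(
            f"{set_a.helix_id}: windows do not overlap at shift {shift}"
        )
    return lo, hi


def overlap_count(
    set_a: GroupConservedSet, set_b: GroupConservedSet, shift: int
) -> int:
    """Aligned pairs: position i in A matched with i - shift in B.

    A negative shift displaces the second family's sequences to the left,
    consistent with the lag convention of the scans.
    """
    lo, hi = _overlap_range(set_a, set_b, shift)
    return sum(
        1 for i in set_a.positions if lo <= i <= hi and (i - shift) in set_b.positions
    )


def overlap_pvalue_exact(L: int, n_a: int, n_b: int, k: int) -> float:
    """P(overlap >= k) when n_a positions are placed uniformly in L slots.

    This is the hypergeometric upper tail, symmetric in which side is
    randomized.
    """
    if n_a > L or n_b > L:
        raise ValueError(f"n_a={n_a}, n_b={n_b} cannot exceed window length L={L}")
    if k < 0 or k > min(n_a, n_b):
        raise ValueError(f"impossible overlap count k={k} for n_a={n_a}, n_b={n_b}")
    return float(hypergeom.sf(k - 1, L, n_a, n_b))


def overlap_pvalue_mc(
    set_a: GroupConservedSet,
    set_b: GroupConservedSet,
    shift: int,
    replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
    randomize: str = "a",
    weights: np.ndarray | None = None,
) -> float:
    """Monte-Carlo one-sided p-value for the observed aligned count.

    Positions of the randomized side are re-placed within the overlapping
    window (uniformly, or following ``weights`` over the overlap slots)
    and the (r + 1)/(n + 1) finite-sample correction is applied.
    """
    if replicates < MIN_MC_REPLICATES:
        raise ValueError(
            f"replicates must be >= {MIN_MC_REPLICATES}, got {replicates}"
        )
    if randomize not in ("a", "b"):
        raise ValueError("randomize must be 'a' or 'b'")
    lo, hi = _overlap_range(set_a, set_b, shift)
    L = hi - lo + 1
    # map both sides into overlap-relative coordinates 0..L-1
    a_idx = np.array(
        sorted(i - lo for i in set_a.positions if lo <= i <= hi), dtype=np.int64
    )
    b_idx = np.array(
        sorted(j - (lo - shift) for j in set_b.positions
               if lo - shift <= j <= hi - shift),
        dtype=np.int64,
    )
    observed = np.intersect1d(a_idx, b_idx).size
    rng = np.random.default_rng(seed)
    moving_n = len(a_idx) if randomize == "a" else len(b_idx)
    fixed = set((b_idx if randomize == "a" else a_idx).tolist())
    p = None
    if weights is not None:
        weights = np.asarray(weights, dtype=np.float64)
        if len(weights) != L:
            raise ValueError(f"weights must have length {L}")
        p = weights / weights.sum()
    hits = 0
    for _ in range(replicates):
        placed = rng.choice(L, size=moving_n, replace=False, p=p)
        if sum(1 for x in placed if x in fixed) >= observed:
            hits += 1
    return (hits + 1) / (replicates + 1)


def overlap_test(
    set_a: GroupConservedSet,
    set_b: GroupConservedSet,
    shift: int = 0,
    replicates: int = DEFAULT_MC_REPLICATES,
    seed: int = 0,
) -> OverlapTest:
    """Full overlap test at one shift: observed count, exact and MC p.

    The exact value conditions on the numbers of positions falling inside
    the overlapping window; the MC engine randomizes each side in turn and
    the reported p is the larger of the two directions.
    """
    lo, hi = _overlap_range(set_a, set_b, shift)
    L = hi - lo + 1
    k = overlap_count(set_a, set_b, shift)
    n_a = sum(1 for i in set_a.positions if lo <= i <= hi)
    n_b = sum(1 for j in set_b.positions if lo - shift <= j <= hi - shift)
    return OverlapTest(
        helix_id=set_a.helix_id,
        shift=shift,
        observed=k,
        overlap_length=L,
        n_a=n_a,
        n_b=n_b,
        p_exact=overlap_pvalue_exact(L, n_a, n_b, k),
        p_mc_randomize_a=overlap_pvalue_mc(
            set_a, set_b, shift, replicates, seed, randomize="a"
        ),
        p_mc_randomize_b=overlap_pvalue_mc(
            set_a, set_b, shift, replicates, seed + 1, randomize="b"
        ),
        mc_replicates=replicates,
        seed=seed,
    )


def detect_group_conserved(
    family: AlignedFamily,
    helix_id: str,
    residue_groups: dict[str, frozenset[str]] | None = None,
    min_group_freq: float = DEFAULT_MIN_GROUP_FREQ,
) -> GroupConservedSet:
    """Window positions conserved as a residue class.

    A position qualifies when the combined frequency of some group's
    residues reaches ``min_group_freq`` (gaps excluded from normalization).
    Curated tables, when available, should be preferred over detection.
    """
    groups = DEFAULT_RESIDUE_GROUPS if residue_groups is None else residue_groups
    if not groups or any(not g for g in groups.values()):
        raise ValueError("residue_groups must be non-empty groups of residues")
    region = family.region(helix_id)
    freq = family.frequency_matrix()[region.start_idx : region.stop_idx]
    masks = {
        name: np.array([aa in members for aa in AMINO_ACIDS])
        for name, members in groups.items()
    }
    positions = set()
    for offset in range(region.length):
        row = freq[offset]
        if np.isnan(row).any():
            continue  # empty column cannot be conserved
        if any(row[mask].sum() >= min_group_freq for mask in masks.values()):
            positions.add(offset + 1)
    return GroupConservedSet(
        family_id=family.family_id,
        helix_id=helix_id,
        positions=frozenset(positions),
        window_length=region.length,
    )


def read_group_conserved_table(
    path: str | Path, family_id: str, window_lengths: dict[str, int]
) -> dict[str, GroupConservedSet]:
    """Read a CSV of curated positions (family_id, helix_id, position).

    Positions are 1-based offsets within each helix window, whose lengths
    are supplied by the caller (typically from the family's regions).
    """
    per_helix: dict[str, set[int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["family_id"] != family_id:
                continue
            per_helix.setdefault(row["helix_id"], set()).add(int(row["position"]))
    return {
        helix: GroupConservedSet(
            family_id=family_id,
            helix_id=helix,
            positions=frozenset(pos),
            window_length=window_lengths[helix],
        )
        for helix, pos in per_helix.items()
    }


def overlap_report(tests: list[OverlapTest]):
    """Tidy per-helix report of overlap tests."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "helix_id": t.helix_id,
                "shift": t.shift,
                "observed": t.observed,
                "overlap_length": t.overlap_length,
                "n_a": t.n_a,
                "n_b": t.n_b,
                "p_exact": t.p_exact,
                "p_mc_randomize_a": t.p_mc_randomize_a,
                "p_mc_randomize_b": t.p_mc_randomize_b,
                "reported_p": t.reported_p,
                "mc_replicates": t.mc_replicates,
                "seed": t.seed,
            }
            for t in tests
        ]
    )
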
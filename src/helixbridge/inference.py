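"""Plausible-peak enumeration and bridge triangulation.

A consensus scan yields a set of *plausible* lags: local maxima of the
trace within a stated fraction (default 70%) of the highest peak. The
direct pairing's plausible set is then reconciled with the two bridge
pairings: any pair of bridge peaks (p against the bridge from the first
family, q from the second) implies a direct shift p - q. Hypotheses are
ranked in three tiers — supported by all three pairings, implied by the
bridge route only, or seen in the direct scan only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lagscan import LagScan

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.7

#: Peak definitions: "local-max" keeps only local maxima of the trace
#: (plateau members all count; an end lag counts when it is >= its single
#: neighbour); "threshold" keeps every lag above the threshold.
PEAK_MODES = ("local-max", "threshold")


@dataclass
class PlausibleSet:
    """Plausible alignment lags for one pairing and helix.

    ``peaks`` maps each plausible lag to its consensus value, carried as
    evidence into triangulation.
    """

    pairing: tuple[str, str]
    helix_id: str
    threshold_fraction: float
    peaks: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def lags(self) -> set[int]:
        return set(self.peaks)

    @property
    def best_lag(self) -> int | None:
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda lag: (self.peaks[lag], -abs(lag)))


@dataclass
class ShiftHypothesis:
    """One candidate shift for the direct family pairing.

    ``tier`` 1: the shift is a direct plausible peak AND is implied by a
    pair of bridge peaks; tier 2: bridge-implied only; tier 3: direct only.
    ``evidence`` carries the consensus values behind the supporting peaks.
    """

    helix_id: str
    shift: int
    tier: int
    support: tuple[str, ...]
    evidence: dict[str, float] = field(default_factory=dict)
    is_preferred: bool = False

    @property
    def score(self) -> float:
        """Combined evidence used only to order hypotheses within a tier."""
        return float(np.prod(list(self.evidence.values()))) if self.evidence else 0.0


def _local_maxima(lags: np.ndarray, values: np.ndarray) -> list[int]:
    """Indices of local maxima; NaN treated as absent (-inf) neighbours."""
    v = np.where(np.isfinite(values), values, -np.inf)
    out = []
    for i in range(len(v)):
        if not np.isfinite(values[i]):
            continue
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < len(v) - 1 else -np.inf
        if v[i] >= left and v[i] >= right:
            out.append(i)
    return out


def plausible_peaks(
    scan: LagScan,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    mode: str = "local-max",
) -> PlausibleSet:
    """Plausible lags: peaks within ``threshold_fraction`` of the maximum.

    A degenerate (flat) scan carries no information and yields an empty
    set with a logged warning.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    if mode not in PEAK_MODES:
        raise ValueError(f"mode must be one of {PEAK_MODES}, got '{mode}'")
    if scan.degenerate:
        logger.warning(
            "%s/%s: degenerate consensus scan, no plausible peaks",
            "-".join(scan.pairing), scan.helix_id,
        )
        return PlausibleSet(
            pairing=scan.pairing,
            helix_id=scan.helix_id,
            threshold_fraction=threshold_fraction,
            degenerate=True,
        )
    finite = np.isfinite(scan.scaled)
    top = scan.scaled[finite].max()
    cut = threshold_fraction * top
    if mode == "local-max":
        candidate_idx = _local_maxima(scan.lags, scan.scaled)
    else:
        candidate_idx = list(np.flatnonzero(finite))
    peaks = {
        int(scan.lags[i]): float(scan.scaled[i])
        for i in candidate_idx
        if scan.scaled[i] >= cut
    }
    return PlausibleSet(
        pairing=scan.pairing,
        helix_id=scan.helix_id,
        threshold_fraction=threshold_fraction,
        peaks=peaks,
    )


def triangulate(
    direct: PlausibleSet,
    a_bridge: PlausibleSet,
    b_bridge: PlausibleSet,
) -> list[ShiftHypothesis]:
    """Rank candidate direct shifts from direct and bridge plausible sets.

    A bridge-peak pair (p, q) — first family against the bridge at p,
    second family against the bridge at q — implies the direct shift
    p - q. Hypotheses satisfying all three plausible sets form tier 1,
    bridge-implied shifts tier 2, direct-only shifts tier 3. Ties in
    evidence are reported, never auto-resolved; ``is_preferred`` marks the
    unique best hypothesis when one exists.
    """
    if direct.helix_id != a_bridge.helix_id or direct.helix_id != b_bridge.helix_id:
        raise ValueError("plausible sets refer to different helices")
    if not (direct.peaks or a_bridge.peaks or b_bridge.peaks):
        raise ValueError(
            f"{direct.helix_id}: all plausible sets are empty, nothing to triangulate"
        )
    implied: dict[int, float] = {}
    for p, ev_p in a_bridge.peaks.items():
        for q, ev_q in b_bridge.peaks.items():
            s = p - q
            implied[s] = max(implied.get(s, 0.0), ev_p * ev_q)

    hypotheses: list[ShiftHypothesis] = []
    for s in sorted(set(direct.peaks) | set(implied)):
        in_direct = s in direct.peaks
        in_bridge = s in implied
        support: list[str] = []
        evidence: dict[str, float] = {}
        if in_direct:
            support.append("direct")
            evidence["direct"] = direct.peaks[s]
        if in_bridge:
            support.extend(["a_bridge", "b_bridge"])
            evidence["bridge"] = implied[s]
        tier = 1 if (in_direct and in_bridge) else (2 if in_bridge else 3)
        hypotheses.append(
            ShiftHypothesis(
                helix_id=direct.helix_id,
                shift=s,
                tier=tier,
                support=tuple(support),
                evidence=evidence,
            )
        )
    hypotheses.sort(key=lambda h: (h.tier, -h.score, abs(h.shift), h.shift))
    if hypotheses:
        best = hypotheses[0]
        tied = [
            h for h in hypotheses[1:] if h.tier == best.tier and h.score == best.score
        ]
        if not tied:
            best.is_preferred = True
    return hypotheses


def renumber(
    hypotheses: list[ShiftHypothesis], reference_shift: int
) -> list[ShiftHypothesis]:
    """Relabel shifts relative to ``reference_shift`` (which becomes 0).

    Reporting convention: the preferred alignment is alignment 0 and the
    alternatives are stated as displacements from it. Applying the
    relabelling twice is the identity, because after the first pass the
    reference hypothesis sits at shift 0.
    """
    return [
        ShiftHypothesis(
            helix_id=h.helix_id,
            shift=h.shift - reference_shift,
            tier=h.tier,
            support=h.support,
            evidence=dict(h.evidence),
            is_preferred=h.is_preferred,
        )
        for h in hypotheses
    ]


def renumber_to_preferred(hypotheses: list[ShiftHypothesis]) -> list[ShiftHypothesis]:
    """Relabel so the preferred hypothesis is reported as alignment 0."""
    preferred = [h for h in hypotheses if h.is_preferred]
    if not preferred:
        return renumber(hypotheses, 0)
    return renumber(hypotheses, preferred[0].shift)
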
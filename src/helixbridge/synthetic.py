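"""Synthetic MSA triples with planted shifts and property architecture.

The generator emulates the statistical structure the alignment method
relies on: two remote families share, through a common ancestor, a
per-position *architecture* — which positions are conserved (low entropy),
which are variable, and a helical-period oscillation of mean
hydrophobicity between the buried and lipid-facing helix faces — even
where their residue identities have diverged beyond direct recognition.

Each helix gets one architecture: a per-position residue frequency vector
with a prescribed entropy and mean hydrophobicity. The three families (two
targets and a bridge) sample their sequences column-independently from
the SAME architecture, displaced by the planted shifts s_A and s_B (bridge
at 0), so the true direct shift is s_A - s_B by construction. Flanking
columns extend far enough that every lag on the scan grid sees a
full-length window. Substitution noise replaces residues uniformly at
random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import FixtureSpecError
from .families import AMINO_ACIDS, AlignedFamily, HelixRegion
from .scales import KYTE_DOOLITTLE

HELICAL_PERIOD = 3.6  # residues per alpha-helical turn
_KD = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS])
_SUPPORT = 8  # residue types mixed per position; caps entropy at 3 bits
_SMALL = [AMINO_ACIDS.index(aa) for aa in "AGSC"]


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic triple.

    Defaults follow the method's operating regime: a 25-residue helix
    window scanned with pad 8, tens of sequences per family, moderate
    substitution noise, conserved positions on the inward face and a
    3.6-residue-period hydrophobicity oscillation mimicking helical facing.
    """

    n_sequences: int = 50
    helix_lengths: dict[str, int] = field(default_factory=lambda: {"TM1": 25})
    shift_a: int = 0
    shift_b: int = 0
    pad: int = 8
    noise: float = 0.1
    conserved_fraction: float = 0.35
    conserved_entropy: tuple[float, float] = (0.3, 1.0)  # bits, sampled per position
    variable_entropy: tuple[float, float] = (2.0, 2.9)
    hydro_mean: float = 1.0
    hydro_amplitude: float = 2.0
    hydro_jitter: float = 0.8
    group_conserved: dict[str, tuple[int, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise < 1.0:
            raise FixtureSpecError(f"noise must be in [0, 1), got {self.noise}")
        if self.n_sequences < 1:
            raise FixtureSpecError("need at least one sequence per family")
        for helix, length in self.helix_lengths.items():
            if length < 3:
                raise FixtureSpecError(f"{helix}: helix length {length} < 3")
            for pos in self.group_conserved.get(helix, ()):
                if not 1 <= pos <= length:
                    raise FixtureSpecError(
                        f"{helix}: group-conserved position {pos} outside window"
                    )
        max_shift = max(abs(self.shift_a), abs(self.shift_b), 1)
        if max_shift > self.pad:
            raise FixtureSpecError(
                f"|shifts| (max {max_shift}) must not exceed pad {self.pad}"
            )


def _entropy_of_mix(eps: float) -> float:
    """Entropy (bits) of (1 - 7e/8) on one residue plus e/8 on 7 others."""
    f_dom = 1.0 - 7.0 * eps / _SUPPORT
    f_min = eps / _SUPPORT
    h = 0.0
    if f_dom > 0:
        h -= f_dom * math.log2(f_dom)
    if f_min > 0:
        h -= 7 * f_min * math.log2(f_min)
    return h


def _mix_for_entropy(target_bits: float) -> float:
    """Mixing weight whose 8-residue mixture has the target entropy."""
    target = min(max(target_bits, 0.0), math.log2(_SUPPORT) - 1e-6)
    if target <= 0.0:
        return 0.0
    return brentq(lambda e: _entropy_of_mix(e) - target, 0.0, 1.0, xtol=1e-10)


def _architecture(
    spec: FixtureSpec, helix_id: str, length: int, rng: np.random.Generator
) -> np.ndarray:
    """(length, 20) per-position frequency vectors for one helix tract."""
    freqs = np.zeros((length, 20))
    phase = rng.uniform(0, 2 * math.pi)
    for t in range(length):
        target_h = (
            spec.hydro_mean
            + spec.hydro_amplitude * math.cos(2 * math.pi * t / HELICAL_PERIOD + phase)
            + rng.normal(0, spec.hydro_jitter)
        )
        if rng.uniform() < spec.conserved_fraction:
            target_bits = rng.uniform(*spec.conserved_entropy)
        else:
            target_bits = rng.uniform(*spec.variable_entropy)
        order = np.argsort(np.abs(_KD - target_h) + rng.uniform(0, 0.3, size=20))
        support = order[:_SUPPORT]
        eps = _mix_for_entropy(target_bits)
        f = np.zeros(20)
        f[support] = eps / _SUPPORT
        f[support[0]] = 1.0 - 7.0 * eps / _SUPPORT
        freqs[t] = f
    return freqs


def _plant_group_conserved(
    freqs: np.ndarray, offsets: tuple[int, ...], window_start: int,
    rng: np.random.Generator,
) -> None:
    """Overwrite positions with compositions conserved in the small group."""
    for w in offsets:
        t = window_start + w - 1
        f = np.zeros(20)
        shares = rng.dirichlet(np.full(len(_SMALL), 2.0))
        f[_SMALL] = shares
        freqs[t] = f


def _sample_family(
    family_id: str,
    arch: dict[str, np.ndarray],
    spec: FixtureSpec,
    shift: int,
    margin: int,
    flank: int,
    rng: np.random.Generator,
) -> AlignedFamily:
    """Sample one family whose content is the architecture displaced by
    ``shift`` (positive shift slides the family's content right)."""
    parts = []
    regions = {}
    col0 = 0
    for helix_id, length in spec.helix_lengths.items():
        freqs = arch[helix_id]
        n_cols = length + 2 * flank
        block = np.empty((spec.n_sequences, n_cols), dtype=np.int64)
        for c in range(n_cols):
            f = freqs[c - shift + margin]
            block[:, c] = rng.choice(20, size=spec.n_sequences, p=f)
        if spec.noise > 0:
            mask = rng.uniform(size=block.shape) < spec.noise
            block[mask] = rng.integers(0, 20, size=int(mask.sum()))
        parts.append(block)
        regions[helix_id] = HelixRegion(
            helix_id=helix_id,
            start_col=col0 + flank + 1,
            end_col=col0 + flank + length,
            ref50_col=col0 + flank + 1 + length // 2,
        )
        col0 += n_cols
    full = np.concatenate(parts, axis=1)
    lookup = np.array(list(AMINO_ACIDS))
    sequences = ["".join(lookup[row]) for row in full]
    ids = [f"{family_id}_{i:03d}" for i in range(spec.n_sequences)]
    return AlignedFamily(
        family_id=family_id, ids=ids, sequences=sequences, regions=regions
    )


def _flank_and_margin(spec: FixtureSpec) -> tuple[int, int]:
    """Flank: columns beside each TM window so every lag sees a full
    window; margin: extra architecture either side absorbing the shifts."""
    flank = spec.pad
    margin = max(abs(spec.shift_a), abs(spec.shift_b), 1)
    return flank, margin


def generate_triple(
    spec: FixtureSpec,
) -> tuple[AlignedFamily, AlignedFamily, AlignedFamily, dict]:
    """Two target families plus a bridge sharing one architecture.

    Returns (family_a, family_b, bridge, truth); the truth record holds
    the planted shifts (direct = shift_a - shift_b), the architecture's
    per-window-position entropy targets, and each family's group-conserved
    window offsets. Deterministic for a fixed spec.
    """
    root = np.random.SeedSequence(spec.seed)
    arch_rng, a_rng, b_rng, g_rng = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    flank, margin = _flank_and_margin(spec)
    arch: dict[str, np.ndarray] = {}
    entropy_targets: dict[str, list[float]] = {}
    for helix_id, length in spec.helix_lengths.items():
        tract = _architecture(spec, helix_id, length + 2 * flank + 2 * margin, arch_rng)
        _plant_group_conserved(
            tract, spec.group_conserved.get(helix_id, ()), margin + flank, arch_rng
        )
        arch[helix_id] = tract
        window = tract[margin + flank : margin + flank + length]
        entropy_targets[helix_id] = [
            float(-(f[f > 0] * np.log2(f[f > 0])).sum()) for f in window
        ]
    fam_a = _sample_family("classA", arch, spec, spec.shift_a, margin, flank, a_rng)
    fam_b = _sample_family("classB", arch, spec, spec.shift_b, margin, flank, b_rng)
    bridge = _sample_family("bridge", arch, spec, 0, margin, flank, g_rng)
    truth = {
        "shift_a": spec.shift_a,
        "shift_b": spec.shift_b,
        "direct_shift": spec.shift_a - spec.shift_b,
        "seed": spec.seed,
        "entropy_targets": entropy_targets,
        "group_conserved": {
            fam.family_id: {
                helix: sorted(
                    w + shift
                    for w in spec.group_conserved.get(helix, ())
                    if 1 <= w + shift <= spec.helix_lengths[helix]
                )
                for helix in spec.helix_lengths
            }
            for fam, shift in ((fam_a, spec.shift_a), (fam_b, spec.shift_b), (bridge, 0))
        },
    }
    return fam_a, fam_b, bridge, truth


def generate_null_pair(
    spec: FixtureSpec,
) -> tuple[AlignedFamily, AlignedFamily]:
    """Two families with independent architectures (negative control).

    Any consensus peak between them is noise; used to check the method
    does not manufacture alignments.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    flank, margin = _flank_and_margin(spec)
    fams = []
    for k, family_id in enumerate(("nullA", "nullB")):
        arch_rng = np.random.default_rng(int(seeds[2 * k]))
        sample_rng = np.random.default_rng(int(seeds[2 * k + 1]))
        arch = {
            helix_id: _architecture(
                spec, helix_id, length + 2 * flank + 2 * margin, arch_rng
            )
            for helix_id, length in spec.helix_lengths.items()
        }
        fams.append(
            _sample_family(family_id, arch, spec, 0, margin, flank, sample_rng)
        )
    return fams[0], fams[1]
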
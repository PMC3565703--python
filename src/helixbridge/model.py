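"""Model/results objects tying the pipeline together.

:class:`BridgeAlignment` holds the data (two target families plus a
bridge family, with their helix annotations) and the analysis settings;
``fit()`` runs every scan, the consensus products, the plausible-peak
enumeration and the triangulation, returning a
:class:`BridgeAlignmentResults` that carries the traces, the ranked shift
hypotheses and the overlap-test interface, with a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .families import AlignedFamily, read_alignment
from .inference import (
    DEFAULT_THRESHOLD_FRACTION,
    PlausibleSet,
    ShiftHypothesis,
    plausible_peaks,
    triangulate,
)
from .lagscan import (
    DEFAULT_PAD,
    LagScan,
    blosum_lag_scan,
    consensus_scan,
    property_lag_scan,
    scans_frame,
)
from .profiles import entropy_profile, hydrophobicity_profile
from .scales import DEFAULT_SCALE
from .stats import (
    DEFAULT_MC_REPLICATES,
    GroupConservedSet,
    OverlapTest,
    detect_group_conserved,
    overlap_test,
)

PAIRING_LABELS = ("direct", "a_bridge", "b_bridge")


class BridgeAlignment:
    """Bridge-mediated alignment model over three aligned families.

    Parameters
    ----------
    family_a, family_b : AlignedFamily
        The two remote families to be aligned (e.g. class A and class B
        GPCR transmembrane alignments).
    bridge : AlignedFamily
        A family with detectable similarity to both, used to triangulate.
    helices : list of str, optional
        Helices to analyse; defaults to those annotated in all three
        families.
    pad : int
        Half-width of the lag grid; pad 8 gives the standard 17 lags.
    threshold_fraction : float
        Plausible-peak cutoff as a fraction of the maximum consensus peak.
    scale_id : str
        Registered hydrophobicity scale for the hydrophobicity track.
    peak_mode : str
        "local-max" (peaks only) or "threshold" (every lag above cutoff).
    """

    def __init__(
        self,
        family_a: AlignedFamily,
        family_b: AlignedFamily,
        bridge: AlignedFamily,
        helices: list[str] | None = None,
        pad: int = DEFAULT_PAD,
        threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
        scale_id: str = DEFAULT_SCALE,
        peak_mode: str = "local-max",
    ) -> None:
        self.family_a = family_a
        self.family_b = family_b
        self.bridge = bridge
        if helices is None:
            helices = sorted(
                set(family_a.regions) & set(family_b.regions) & set(bridge.regions)
            )
        if not helices:
            raise ValueError("no helix annotated in all three families")
        self.helices = list(helices)
        self.pad = pad
        self.threshold_fraction = threshold_fraction
        self.scale_id = scale_id
        self.peak_mode = peak_mode

    @classmethod
    def from_files(
        cls,
        msa_a: str | Path,
        msa_b: str | Path,
        msa_bridge: str | Path,
        region_config: str | Path,
        family_ids: tuple[str, str, str] = ("classA", "classB", "bridge"),
        **kwargs,
    ) -> "BridgeAlignment":
        """Build the model from three aligned FASTAs and one region table."""
        fam_a = read_alignment(msa_a, family_ids[0], region_config)
        fam_b = read_alignment(msa_b, family_ids[1], region_config)
        bridge = read_alignment(msa_bridge, family_ids[2], region_config)
        return cls(fam_a, fam_b, bridge, **kwargs)

    def _pairs(self) -> dict[str, tuple[AlignedFamily, AlignedFamily]]:
        return {
            "direct": (self.family_a, self.family_b),
            "a_bridge": (self.family_a, self.bridge),
            "b_bridge": (self.family_b, self.bridge),
        }

    def fit(self) -> "BridgeAlignmentResults":
        """Run all scans, consensus products and triangulation."""
        scans: dict[tuple[str, str, str], LagScan] = {}
        plausible: dict[str, dict[str, PlausibleSet]] = {}
        hypotheses: dict[str, list[ShiftHypothesis]] = {}
        for helix in self.helices:
            plausible[helix] = {}
            for label, (fx, fy) in self._pairs().items():
                blosum = blosum_lag_scan(fx, fy, helix, pad=self.pad)
                ent = property_lag_scan(
                    entropy_profile(fx, helix, pad=self.pad),
                    entropy_profile(fy, helix, pad=self.pad),
                    pad=self.pad,
                )
                hyd = property_lag_scan(
                    hydrophobicity_profile(fx, helix, pad=self.pad, scale_id=self.scale_id),
                    hydrophobicity_profile(fy, helix, pad=self.pad, scale_id=self.scale_id),
                    pad=self.pad,
                )
                cons = consensus_scan(blosum, ent, hyd)
                for scan in (blosum, ent, hyd, cons):
                    scans[(helix, label, scan.measure)] = scan
                plausible[helix][label] = plausible_peaks(
                    cons, self.threshold_fraction, mode=self.peak_mode
                )
            hypotheses[helix] = triangulate(
                plausible[helix]["direct"],
                plausible[helix]["a_bridge"],
                plausible[helix]["b_bridge"],
            )
        return BridgeAlignmentResults(
            model=self, scans=scans, plausible=plausible, hypotheses=hypotheses
        )


@dataclass
class BridgeAlignmentResults:
    """Fitted scans, plausible sets and ranked shift hypotheses."""

    model: BridgeAlignment
    scans: dict[tuple[str, str, str], LagScan]
    plausible: dict[str, dict[str, PlausibleSet]]
    hypotheses: dict[str, list[ShiftHypothesis]]
    overlap_tests: list[OverlapTest] = field(default_factory=list)

    def scan(self, helix: str, pairing: str, measure: str) -> LagScan:
        """One trace; pairing in {direct, a_bridge, b_bridge}."""
        return self.scans[(helix, pairing, measure)]

    def preferred_shift(self, helix: str) -> int | None:
        """The unique best-supported direct shift, if one exists."""
        for h in self.hypotheses[helix]:
            if h.is_preferred:
                return h.shift
        return None

    def scans_frame(self) -> pd.DataFrame:
        return scans_frame(list(self.scans.values()))

    def consensus_frame(self) -> pd.DataFrame:
        df = self.scans_frame()
        return df[df["measure"] == "consensus"].reset_index(drop=True)

    # -- statistical validation -------------------------------------------

    def run_overlap_tests(
        self,
        group_a: dict[str, GroupConservedSet] | None = None,
        group_b: dict[str, GroupConservedSet] | None = None,
        shift: int | None = None,
        replicates: int = DEFAULT_MC_REPLICATES,
        seed: int = 0,
    ) -> list[OverlapTest]:
        """Overlap tests per helix at the preferred (or given) shift.

        Curated group-conserved tables win when supplied; otherwise
        positions are detected from the alignments.
        """
        tests = []
        for helix in self.model.helices:
            use_shift = shift if shift is not None else self.preferred_shift(helix)
            if use_shift is None:
                continue
            set_a = (group_a or {}).get(helix) or detect_group_conserved(
                self.model.family_a, helix
            )
            set_b = (group_b or {}).get(helix) or detect_group_conserved(
                self.model.family_b, helix
            )
            tests.append(
                overlap_test(
                    set_a, set_b, use_shift, replicates=replicates, seed=seed
                )
            )
        self.overlap_tests = tests
        return tests

    # -- reporting ---------------------------------------------------------

    def hypotheses_records(self) -> list[dict]:
        records = []
        for helix in self.model.helices:
            for h in self.hypotheses[helix]:
                records.append(
                    {
                        "helix_id": helix,
                        "shift": h.shift,
                        "tier": h.tier,
                        "support": list(h.support),
                        "evidence": h.evidence,
                        "is_preferred": h.is_preferred,
                    }
                )
        return records

    def summary(self) -> str:
        """Human-readable per-helix report.

        For each helix: the best lag per measure and pairing, the
        consensus plausible sets, and the triangulated hypotheses by tier.
        """
        lines = []
        width = 72
        lines.append("Bridge-mediated helix alignment".center(width))
        lines.append("=" * width)
        lines.append(
            f"families: {self.model.family_a.family_id} vs "
            f"{self.model.family_b.family_id} via {self.model.bridge.family_id}"
        )
        lines.append(
            f"lags: -{self.model.pad}..+{self.model.pad} "
            f"({2 * self.model.pad + 1}); plausible-peak cutoff: "
            f"{self.model.threshold_fraction:.0%} of max; "
            f"hydrophobicity scale: {self.model.scale_id}"
        )
        for helix in self.model.helices:
            lines.append("-" * width)
            lines.append(f"{helix}")
            header = f"  {'measure':<16}" + "".join(
                f"{label:>12}" for label in PAIRING_LABELS
            )
            lines.append(header + "   (best lag)")
            for measure in ("blosum", "entropy", "hydrophobicity", "consensus"):
                row = f"  {measure:<16}"
                for label in PAIRING_LABELS:
                    scan = self.scans[(helix, label, measure)]
                    row += f"{scan.argmax_lag:>+12d}"
                lines.append(row)
            for label in PAIRING_LABELS:
                ps = self.plausible[helix][label]
                peaks = ", ".join(
                    f"{lag:+d} ({val:.2f})" for lag, val in sorted(ps.peaks.items())
                ) or "(none)"
                lines.append(f"  plausible[{label}]: {peaks}")
            for h in self.hypotheses[helix]:
                mark = " <- preferred" if h.is_preferred else ""
                lines.append(
                    f"  hypothesis shift {h.shift:+d}  tier {h.tier}  "
                    f"support={','.join(h.support)}{mark}"
                )
            for t in self.overlap_tests:
                if t.helix_id == helix:
                    lines.append(
                        f"  overlap test @ shift {t.shift:+d}: observed {t.observed} "
                        f"of {t.n_a}x{t.n_b} in L={t.overlap_length}; "
                        f"p_exact={t.p_exact:.4f} reported_p={t.reported_p:.4f}"
                    )
        lines.append("=" * width)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write scans.tsv, consensus.tsv and hypotheses.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scans": outdir / "scans.tsv",
            "consensus": outdir / "consensus.tsv",
            "hypotheses": outdir / "hypotheses.json",
        }
        self.scans_frame().to_csv(paths["scans"], sep="\t", index=False)
        self.consensus_frame().to_csv(paths["consensus"], sep="\t", index=False)
        with open(paths["hypotheses"], "w") as fh:
            json.dump(self.hypotheses_records(), fh, indent=2)
        return paths

    def plot_helix(self, helix: str):
        """Quick-look 4x3 panel of scaled traces for one helix.

        Rows: blosum, entropy, hydrophobicity, consensus; columns: the
        three pairings. Requires matplotlib.
        """
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        measures = ("blosum", "entropy", "hydrophobicity", "consensus")
        fig, axes = plt.subplots(4, 3, figsize=(10, 10), sharex=True)
        for i, measure in enumerate(measures):
            for j, label in enumerate(PAIRING_LABELS):
                scan = self.scans[(helix, label, measure)]
                ax = axes[i, j]
                ax.plot(scan.lags, scan.scaled, marker="o", ms=3)
                if i == 0:
                    ax.set_title(label)
                if j == 0:
                    ax.set_ylabel(measure)
        fig.suptitle(f"{helix}: scaled lag traces")
        fig.tight_layout()
        return fig
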
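"""The scoring core: lag grids, pair scores, scans, scaling, consensus."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from helixbridge.errors import LagGridMismatchError, MeasureMismatchError
from helixbridge.families import AMINO_ACIDS, AlignedFamily, HelixRegion
from helixbridge.lagscan import (
    blosum_lag_scan,
    consensus_scan,
    enumerate_lags,
    profile_pair_score,
    property_lag_scan,
    unit_scale,
)
from helixbridge.profiles import PropertyProfile, entropy_profile
from helixbridge.synthetic import FixtureSpec, generate_triple


def onehot(aa):
    v = np.zeros(20)
    v[AMINO_ACIDS.index(aa)] = 1.0
    return v


class TestLagGrid:
    @pytest.mark.parametrize("pad,expected_len", [(8, 17), (0, 1), (2, 5)])
    def test_grid_size(self, pad, expected_len):
        lags = enumerate_lags(pad)
        assert len(lags) == expected_len
        assert lags[0] == -pad and lags[-1] == pad

    def test_pad_two_values(self):
        assert enumerate_lags(2).tolist() == [-2, -1, 0, 1, 2]

    def test_negative_pad_rejected(self):
        with pytest.raises(ValueError):
            enumerate_lags(-1)


class TestProfilePairScore:
    def test_pure_column_scores_match_blosum62_entries(self):
        assert profile_pair_score(onehot("W"), onehot("W")) == 11
        assert profile_pair_score(onehot("A"), onehot("A")) == 4

    def test_mixed_column_is_frequency_weighted(self):
        mix = 0.5 * onehot("A") + 0.5 * onehot("G")
        # 0.5*M(A,A) + 0.5*M(G,A) = 0.5*4 + 0.5*0
        assert profile_pair_score(mix, onehot("A")) == pytest.approx(2.0)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            profile_pair_score(2 * onehot("A"), onehot("A"))


class TestUnitScale:
    @pytest.mark.parametrize(
        "raw,expected",
        [([2, 4, 6], [0, 0.5, 1]), ([-1, 0, 1], [0, 0.5, 1])],
    )
    def test_minmax(self, raw, expected):
        scaled, degenerate = unit_scale(np.array(raw, dtype=float))
        assert scaled == pytest.approx(expected)
        assert not degenerate

    def test_flat_trace_degenerate(self):
        scaled, degenerate = unit_scale(np.array([5.0, 5.0, 5.0]))
        assert scaled == pytest.approx([0, 0, 0])
        assert degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            unit_scale(np.array([]))


def _single_seq_family(seq, family_id, start, end):
    return AlignedFamily(
        family_id, ["only"], [seq],
        regions={"TM1": HelixRegion("TM1", start, end)},
    )


class TestBlosumScan:
    def test_identical_families_peak_at_zero(self, planted_triple):
        fam_a, _, _, _ = planted_triple
        scan = blosum_lag_scan(fam_a, fam_a, "TM1")
        assert scan.argmax_lag == 0
        assert scan.scaled_at(0) == pytest.approx(1.0)

    def test_planted_shift_recovered(self, planted_triple):
        fam_a, _, bridge, truth = planted_triple
        scan = blosum_lag_scan(fam_a, bridge, "TM1")
        assert scan.argmax_lag == truth["shift_a"]

    def test_swap_symmetry_raw(self, planted_triple):
        fam_a, fam_b, _, _ = planted_triple
        ab = blosum_lag_scan(fam_a, fam_b, "TM1")
        ba = blosum_lag_scan(fam_b, fam_a, "TM1")
        for lag in ab.lags:
            assert ab.raw_at(int(lag)) == pytest.approx(
                ba.raw_at(-int(lag)), abs=1e-9
            )

    def test_single_sequence_reduces_to_pairwise_window_score(self):
        """Independent oracle: direct ungapped BLOSUM62 summation."""
        rng = np.random.default_rng(42)
        letters = np.array(list(AMINO_ACIDS))
        sx = "".join(rng.choice(letters, size=30))
        sy = "".join(rng.choice(letters, size=30))
        fx = _single_seq_family(sx, "x", 11, 20)
        fy = _single_seq_family(sy, "y", 11, 20)
        scan = blosum_lag_scan(fx, fy, "TM1", pad=4)
        mat = substitution_matrices.load("BLOSUM62")

        def window_score(a, b, a0, b0, w, n):
            total, used = 0.0, 0
            for j in range(w):
                if 0 <= b0 + j < n:
                    total += mat[a[a0 + j], b[b0 + j]]
                    used += 1
            return total if used >= 3 else np.nan

        for lag in scan.lags:
            fwd = window_score(sx, sy, 10, 10 - int(lag), 10, 30)
            rev = window_score(sy, sx, 10, 10 + int(lag), 10, 30)
            assert scan.raw_at(int(lag)) == pytest.approx(
                np.nanmean([fwd, rev]), abs=1e-9
            )

    def test_truncated_lags_flagged_at_alignment_edge(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        fx = _single_seq_family(seq, "x", 6, 15)
        fy = _single_seq_family(seq, "y", 6, 15)
        scan = blosum_lag_scan(fx, fy, "TM1", pad=8)
        assert "truncated" in scan.flags.get(8, ())
        assert scan.argmax_lag == 0


class TestPropertyScan:
    def _profile(self, values, family_id, measure="entropy"):
        n = len(values)
        return PropertyProfile(family_id, "TM1", measure,
                               np.arange(1, n + 1), np.asarray(values, float),
                               tm_start_col=5, tm_end_col=n - 4)

    def test_exact_copy_has_unit_correlation_at_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        px = self._profile(vals, "x")
        py = self._profile(vals, "y")
        scan = property_lag_scan(px, py, pad=4)
        assert scan.raw_at(0) == pytest.approx(1.0)

    def test_negated_copy_has_minus_one_at_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        scan = property_lag_scan(
            self._profile(vals, "x"), self._profile(-vals, "y"), pad=4
        )
        assert scan.raw_at(0) == pytest.approx(-1.0)

    def test_constant_profile_degenerate_zero_correlations(self):
        rng = np.random.default_rng(2)
        scan = property_lag_scan(
            self._profile(rng.normal(size=30), "x"),
            self._profile(np.ones(30), "y"),
            pad=4,
        )
        assert np.allclose(scan.raw[np.isfinite(scan.raw)], 0.0)
        assert scan.degenerate
        assert any("zero_variance" in f for f in scan.flags.values())

    def test_measure_mismatch_rejected(self):
        with pytest.raises(MeasureMismatchError):
            property_lag_scan(
                self._profile(np.ones(30), "x", "entropy"),
                self._profile(np.ones(30), "y", "hydrophobicity"),
            )


class TestConsensus:
    def test_product_of_components(self):
        from helixbridge.lagscan import LagScan

        lags = np.array([-1, 0, 1])

        def mk(measure, scaled):
            arr = np.asarray(scaled, float)
            return LagScan(("x", "y"), "TM1", measure, lags, arr.copy(), arr)

        cons = consensus_scan(
            mk("blosum", [1.0, 0.5, 0.0]),
            mk("entropy", [1.0, 0.5, 0.3]),
            mk("hydrophobicity", [1.0, 0.5, 0.9]),
        )
        assert cons.scaled == pytest.approx([1.0, 0.125, 0.0])

    def test_consensus_bounded_by_components(self, planted_triple):
        fam_a, fam_b, _, _ = planted_triple
        from helixbridge.profiles import hydrophobicity_profile

        b = blosum_lag_scan(fam_a, fam_b, "TM1")
        e = property_lag_scan(
            entropy_profile(fam_a, "TM1", pad=8), entropy_profile(fam_b, "TM1", pad=8)
        )
        h = property_lag_scan(
            hydrophobicity_profile(fam_a, "TM1", pad=8),
            hydrophobicity_profile(fam_b, "TM1", pad=8),
        )
        cons = consensus_scan(b, e, h)
        for comp in (b, e, h):
            ok = np.isfinite(cons.scaled) & np.isfinite(comp.scaled)
            assert np.all(cons.scaled[ok] <= comp.scaled[ok] + 1e-12)

    def test_mismatched_grids_rejected(self):
        from helixbridge.lagscan import LagScan

        def mk(measure, lags):
            arr = np.zeros(len(lags))
            return LagScan(("x", "y"), "TM1", measure, np.array(lags), arr, arr)

        with pytest.raises(LagGridMismatchError):
            consensus_scan(
                mk("blosum", [-1, 0, 1]),
                mk("entropy", [0, 1, 2]),
                mk("hydrophobicity", [-1, 0, 1]),
            )


def test_planted_lag_recovery_rate():
    """Consensus argmax equals the planted shift in >=90% of replicates."""
    rng = np.random.default_rng(123)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        s = int(rng.integers(-8, 9))
        spec = FixtureSpec(
            n_sequences=50, helix_lengths={"TM1": 25},
            shift_a=s, shift_b=0, noise=0.1,
            seed=int(rng.integers(2**31)),
        )
        fam_a, _, bridge, _ = generate_triple(spec)
        from helixbridge.profiles import hydrophobicity_profile

        b = blosum_lag_scan(fam_a, bridge, "TM1")
        e = property_lag_scan(
            entropy_profile(fam_a, "TM1", pad=8),
            entropy_profile(bridge, "TM1", pad=8),
        )
        h = property_lag_scan(
            hydrophobicity_profile(fam_a, "TM1", pad=8),
            hydrophobicity_profile(bridge, "TM1", pad=8),
        )
        if consensus_scan(b, e, h).argmax_lag == s:
            hits += 1
    assert hits >= 0.9 * n_rep
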
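"""Aggregation tracks, hotspots, net charge, and isoelectric point."""

import numpy as np
import pytest

from abdev.biophys import (
    ChargeModel,
    PropensityScales,
    aggregation_profile,
    conformational_profile,
    hotspots,
    intrinsic_profile,
    isoelectric_point,
    net_charge,
    surface_profile,
    window_profile,
)
from abdev.errors import ConfigError, DataError
from abdev.structure import ExposureProfile, default_exposure

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestIntrinsic:
    def test_homopolymer_track_is_constant(self):
        track = intrinsic_profile("VVVVVV")
        assert np.allclose(track, track[0])

    def test_valine_more_prone_than_lysine(self):
        scales = PropensityScales()
        assert scales.intrinsic("V") > scales.intrinsic("K")

    def test_zero_weights_zero_track(self):
        scales = PropensityScales(w_h=0, w_b=0, w_a=0, w_q=0)
        assert np.allclose(intrinsic_profile("ACDEFG", scales), 0.0)

    def test_unknown_residue_contributes_zero_with_warning(self):
        with pytest.warns(UserWarning):
            track = intrinsic_profile("AXA")
        assert track[1] == 0.0


class TestWindow:
    def test_constant_track_mean_and_total(self):
        track = np.full(10, 2.5)
        A, A_tot = window_profile(track, 7)
        assert np.allclose(A, 2.5)
        assert A_tot == pytest.approx(25.0)

    def test_matches_direct_resummation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            track = rng.normal(size=rng.integers(8, 40))
            A, _ = window_profile(track, 7)
            for i in range(len(track)):
                lo, hi = max(0, i - 3), min(len(track), i + 4)
                assert A[i] == pytest.approx(track[lo:hi].mean())

    def test_all_negative_track_has_zero_total(self):
        _, A_tot = window_profile(np.full(12, -1.0), 7)
        assert A_tot == 0.0

    def test_window_longer_than_sequence_degenerates(self):
        track = np.array([1.0, -1.0, 3.0])
        A, _ = window_profile(track, 7)
        assert np.allclose(A, 1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigError):
            window_profile(np.ones(5), 4)


class TestConformational:
    def test_full_exposure_leaves_track_unchanged(self):
        A = np.array([1.0, -2.0, 0.5])
        S, _ = conformational_profile(A, ExposureProfile(chain="x", relative=(1.0, 1.0, 1.0)))
        assert np.allclose(S, A)

    def test_fully_buried_zero_total(self):
        A = np.array([1.0, 2.0, 3.0])
        _, S_tot = conformational_profile(A, ExposureProfile(chain="x", relative=(0.0, 0.0, 0.0)))
        assert S_tot == 0.0

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=15)
        rel = tuple(rng.uniform(0, 1, size=15))
        S, S_tot = conformational_profile(A, ExposureProfile(chain="x", relative=rel))
        assert np.allclose(S, A * np.array(rel))
        assert S_tot == pytest.approx(np.maximum(S, 0).sum())

    def test_s_tot_bounded_by_a_tot_for_nonnegative_tracks(self):
        rng = np.random.default_rng(3)
        A = np.abs(rng.normal(size=20))
        rel = tuple(rng.uniform(0, 1, size=20))
        _, A_tot = window_profile(A, 1)
        _, S_tot = conformational_profile(A, ExposureProfile(chain="x", relative=rel))
        assert S_tot <= A_tot + 1e-9


class TestSurface:
    def test_single_residue_chain(self):
        a = np.array([1.7])
        T, T_tot = surface_profile(a, ExposureProfile(chain="x", relative=(0.5,)))
        assert T[0] == pytest.approx(0.85)
        assert T_tot == pytest.approx(0.85)

    def test_sequence_window_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=25)
        rel = tuple(rng.uniform(0, 1, size=25))
        T, _ = surface_profile(a, ExposureProfile(chain="x", relative=rel), seq_window=4)
        contrib = a * np.array(rel)
        for i in range(25):
            lo, hi = max(0, i - 4), min(25, i + 5)
            assert T[i] == pytest.approx(contrib[lo:hi].sum())

    def test_zero_exposure_zero_total(self):
        a = np.ones(10)
        _, T_tot = surface_profile(a, ExposureProfile(chain="x", relative=(0.0,) * 10))
        assert T_tot == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ConfigError):
            surface_profile(np.ones(3), default_exposure(3), radius=0.0)


class TestHotspots:
    def test_planted_block_recovered(self):
        rng = np.random.default_rng(5)
        track = rng.normal(0.0, 0.1, size=40)
        track[18:23] += 5.0
        spots = hotspots(track, threshold_sd=1.0, min_run=3)
        assert len(spots) == 1
        start, end, _, peak = spots[0]
        assert (start, end) == (19, 23)
        assert peak == pytest.approx(track[18:23].max())

    def test_constant_track_has_no_hotspots(self):
        assert hotspots(np.full(10, 3.0)) == []

    def test_short_runs_ignored(self):
        track = np.zeros(20)
        track[5:7] = 10.0  # run of 2 < min_run 3
        assert hotspots(track, threshold_sd=1.0, min_run=3) == []


class TestCharge:
    def test_triglycine_charge_at_ph7(self):
        # only termini ionize: 1/(1+10^(7-8.6)) - 1/(1+10^(3.6-7))
        expected = 1 / (1 + 10 ** (7 - 8.6)) - 1 / (1 + 10 ** (3.6 - 7))
        assert net_charge("GGG", 7.0) == pytest.approx(expected)
        assert net_charge("GGG", 7.0) == pytest.approx(-0.024, abs=5e-4)

    def test_extreme_acid_limit_counts_basic_groups(self):
        seq = "GKRHG"
        charge = net_charge(seq, 1.0)
        assert charge == pytest.approx(4.0, abs=0.01)  # K, R, H, N-term

    def test_removing_arginine_decreases_charge_at_every_ph(self):
        for ph in np.arange(1.0, 13.5, 0.5):
            assert net_charge("ARA", ph) > net_charge("AGA", ph)

    def test_vectorised_over_ph(self):
        grid = np.linspace(2, 12, 50)
        values = net_charge("ACDKY", grid)
        assert values.shape == grid.shape
        assert np.all(np.diff(values) < 0)  # monotone decreasing in pH


class TestIsoelectricPoint:
    def test_triglycine_midpoint_exact(self):
        assert isoelectric_point("GGG") == pytest.approx((3.6 + 8.6) / 2, abs=0.01)
        assert round(isoelectric_point("GGG"), 2) == 6.10

    def test_zero_charge_at_pi(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = "".join(rng.choice(list(AAS), 30))
            pi = isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 1e-3

    def test_bisection_matches_grid_scan(self):
        """pI agrees with a 0.001-step scan for the zero crossing."""
        rng = np.random.default_rng(7)
        grid = np.arange(0.001, 14.0, 0.001)
        for _ in range(100):
            seq = "".join(rng.choice(list(AAS), rng.integers(5, 40)))
            pi = isoelectric_point(seq)
            charges = net_charge(seq, grid)
            crossing = grid[np.argmin(np.abs(charges))]
            assert abs(pi - crossing) < 0.01

    def test_removing_basic_residue_lowers_pi(self):
        parent = "AKRAKAGHA"
        for removed in ("AKRAKAGHA".replace("R", "G", 1), parent.replace("K", "A", 1)):
            assert isoelectric_point(removed) < isoelectric_point(parent)

    def test_multi_chain_termini_counted_per_chain(self):
        single = isoelectric_point("GG")
        paired = isoelectric_point(["GG", "GG"])
        assert paired == pytest.approx(single, abs=0.01)


class TestAggregationProfileBundle:
    def test_hexavaline_insertion_raises_a_tot(self):
        background = "GQEGQEGQEGQEGQEGQEGQE"
        inserted = background[:10] + "VVVVVV" + background[10:]
        base = aggregation_profile(background)
        more = aggregation_profile(inserted)
        assert more.A_tot > base.A_tot

    def test_hydrophobic_to_serine_never_raises_totals(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = list("".join(rng.choice(list(AAS), 30)))
            idx = [i for i, aa in enumerate(seq) if aa in "ILVFMW"]
            if not idx:
                continue
            i = idx[rng.integers(len(idx))]
            variant = seq.copy()
            variant[i] = "S"
            p0 = aggregation_profile("".join(seq), exposure=default_exposure(30))
            p1 = aggregation_profile("".join(variant), exposure=default_exposure(30))
            assert p1.A_tot <= p0.A_tot + 1e-9
            assert p1.T_tot <= p0.T_tot + 1e-9
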
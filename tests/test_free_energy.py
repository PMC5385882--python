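"""Umbrella windows, WHAM, force curves, unfolded state and ΔG."""

import math

import numpy as np
import pytest

from rnacg.constants import KB, T_REF
from rnacg.fixtures import make_duplex, make_hairpin, sample_boltzmann_1d
from rnacg.free_energy import (FreeEnergyProfile, PullConfig, UmbrellaWindow,
                               _PullBias, bootstrap_error, correlation_report,
                               delta_g_fold, find_unfolded_state, force_curve,
                               load_reference_table, reaction_coordinate,
                               setup_windows, wham)

KT = KB * T_REF


def _double_well(r):
    return (1.5 * ((r - 10) / 4) ** 4
            - 2.0 * math.exp(-((r - 7) / 1.5) ** 2)
            - 1.2 * math.exp(-((r - 13) / 1.5) ** 2))


def _sampled_windows(n_per=100_000, centers=(4, 7, 10, 13, 16), k=1.0):
    return [UmbrellaWindow(c, k, sample_boltzmann_1d(
        _double_well, T_REF, n_per, seed=100 + i, bias=(c, k), domain=(2, 18)))
        for i, c in enumerate(centers)]


class TestWindows:
    def test_printed_final_centers(self):
        assert setup_windows(18)[-1].center == pytest.approx(106.5)
        assert setup_windows(52)[-1].center == pytest.approx(307.5)

    def test_window_count_on_unit_grid(self):
        w = setup_windows(18)
        assert len(w) == int(w[-1].center - 5.5 + 1)

    def test_override_and_validation(self):
        w = setup_windows(12, PullConfig(max_center=76.5))
        assert w[-1].center == pytest.approx(76.5)
        with pytest.raises(ValueError):
            setup_windows(1)
        with pytest.raises(ValueError):
            PullConfig(spacing=-1.0)


class TestReactionCoordinate:
    def test_hairpin_terminal_sugars(self):
        s = make_hairpin("GCGCAAAAGCGC", stem=4)
        i = s.bead_index("A", 0, "S")
        j = s.bead_index("A", 11, "S")
        expected = float(np.linalg.norm(s.coords[j] - s.coords[i]))
        assert reaction_coordinate(s, "hairpin") == pytest.approx(expected)

    def test_rotation_invariance(self):
        s = make_hairpin("GCGCAAAAGCGC", stem=4)
        r0 = reaction_coordinate(s, "hairpin")
        th = 0.8
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        s2 = s.with_coords(s.coords @ rot.T + [5.0, 1.0, -2.0])
        assert reaction_coordinate(s2, "hairpin") == pytest.approx(r0)

    def test_duplex_hand_computed(self):
        s = make_duplex("GCGC")
        i = s.bead_index("A", 0, "S")
        j = s.bead_index("B", 3, "S")
        expected = float(np.linalg.norm(s.coords[j] - s.coords[i]))
        assert reaction_coordinate(s, "duplex") == pytest.approx(expected)

    def test_bias_convention(self):
        """k (r - c)^2: zero at the center, 4.0 at 2 Å offset with k=1."""
        s = make_hairpin("GCGCAAAAGCGC", stem=4)
        r0 = reaction_coordinate(s, "hairpin")
        bias = _PullBias(s, "hairpin", center=r0, spring_k=1.0)
        e0, _ = bias(s.coords)
        assert e0 == pytest.approx(0.0, abs=1e-12)
        bias2 = _PullBias(s, "hairpin", center=r0 - 2.0, spring_k=1.0)
        e2, _ = bias2(s.coords)
        assert e2 == pytest.approx(4.0, abs=1e-9)


class TestWham:
    def test_single_unbiased_window_degenerates_to_histogram(self):
        s = sample_boltzmann_1d(_double_well, T_REF, 200_000, seed=1,
                                domain=(2, 18))
        prof = wham([UmbrellaWindow(10.0, 0.0, s)], bin_width=0.25)
        counts, edges = np.histogram(s, bins=np.arange(s.min(), s.max() + 0.25,
                                                       0.25))
        ref = -KT * np.log(np.maximum(counts, 1e-300) / counts.max())
        n = min(len(ref), len(prof.omega))
        sel = counts[:n] > 50
        diff = prof.omega[:n][sel] - ref[:n][sel]
        assert np.std(diff) < 0.05  # equal up to an additive constant

    def test_double_well_recovered_within_tolerance(self):
        """5 windows x 1e5 exact samples: RMS error <= 0.2 kcal/mol."""
        prof = wham(_sampled_windows(), bin_width=0.2)
        truth = np.array([_double_well(r) for r in prof.r])
        truth -= truth.min()
        sel = np.isfinite(prof.omega) & (truth < 6.0)
        shift = np.mean(prof.omega[sel] - truth[sel])
        rms = np.sqrt(np.mean((prof.omega[sel] - truth[sel] - shift) ** 2))
        assert rms <= 0.2

    def test_bin_resolution_stability(self):
        wins = _sampled_windows(n_per=40_000)
        p1 = wham(wins, bin_width=0.2)
        p2 = wham(wins, bin_width=0.1)
        interp = np.interp(p1.r, p2.r, p2.omega)
        sel = np.isfinite(interp) & np.isfinite(p1.omega) & (p1.omega < 6)
        assert np.nanmax(np.abs(p1.omega[sel] - interp[sel])) < 0.25

    def test_non_overlapping_windows_error(self):
        w1 = UmbrellaWindow(5.0, 1.0, np.linspace(4.8, 5.2, 100))
        w2 = UmbrellaWindow(12.0, 1.0, np.linspace(11.8, 12.2, 100))
        with pytest.raises(ValueError, match="overlap"):
            wham([w1, w2])

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            wham([])


class TestBootstrap:
    def test_single_replicate_flagged(self):
        prof, flags = bootstrap_error(_sampled_windows(n_per=5000), n_boot=1)
        assert not flags["sufficient"]
        assert np.all(prof.error == 0.0)

    def test_deterministic_under_seed(self):
        wins = _sampled_windows(n_per=5000)
        p1, _ = bootstrap_error(wins, n_boot=8, seed=3)
        p2, _ = bootstrap_error(wins, n_boot=8, seed=3)
        np.testing.assert_array_equal(p1.error, p2.error)

    def test_uncertainty_shrinks_with_samples(self):
        small = _sampled_windows(n_per=2000)
        big = _sampled_windows(n_per=32_000)
        ps, _ = bootstrap_error(small, n_boot=12, seed=4)
        pb, _ = bootstrap_error(big, n_boot=12, seed=4)
        med_s = np.median(ps.error[ps.error > 0])
        med_b = np.median(pb.error[pb.error > 0])
        # 16x the samples: errors should drop by roughly 1/4
        assert med_b < 0.6 * med_s


class TestForceCurve:
    def test_linear_profile_constant_force(self):
        r = np.arange(0, 50, 0.5)
        prof = FreeEnergyProfile(r, 0.7 * r)
        f = force_curve(prof)
        np.testing.assert_allclose(f, 0.7, rtol=1e-9)

    def test_quadratic_profile_linear_force(self):
        r = np.arange(0, 50, 0.5)
        prof = FreeEnergyProfile(r, 0.1 * r ** 2)
        f = force_curve(prof)
        # running average of a linear function is the function itself
        np.testing.assert_allclose(f[5:-5], 0.2 * r[5:-5], rtol=1e-6)

    def test_smoothed_sine_matches_analytic(self):
        r = np.arange(0, 60, 0.25)
        prof = FreeEnergyProfile(r, np.sin(0.5 * r))
        f = force_curve(prof, smoothing=4.0)
        half = 8  # 2 Å / 0.25
        w = 2 * half + 1
        # analytic running mean of cos: sinc-attenuated cosine
        atten = np.sin(0.5 * 0.25 * w / 2) / (w * math.sin(0.5 * 0.25 / 2))
        expect = 0.5 * np.cos(0.5 * r) * atten
        np.testing.assert_allclose(f[half:-half], expect[half:-half], atol=0.01)

    def test_grid_too_coarse(self):
        prof = FreeEnergyProfile(np.arange(0, 50, 6.0),
                                 np.zeros(9))
        with pytest.raises(ValueError, match="coarse"):
            force_curve(prof)


def _plateau_profile():
    """Well at 10 Å, flat 30-60 Å, steep rise beyond 60 Å."""
    r = np.arange(2, 80, 0.5)
    w = np.where(r < 20, 0.05 * (r - 10) ** 2,
                 np.where(r < 60, 5.0, 5.0 + 0.8 * (r - 60) ** 2))
    w = w - w.min()
    return FreeEnergyProfile(r, w)


class TestUnfoldedState:
    def test_constructed_plateau_endpoint(self):
        prof = _plateau_profile()
        f = force_curve(prof)
        r_u, w_u = find_unfolded_state(prof, f, threshold=0.1)
        assert 55.0 <= r_u <= 62.0

    def test_steep_convex_profile_errors(self):
        r = np.arange(2, 40, 0.5)
        prof = FreeEnergyProfile(r, 2.0 * r)
        f = force_curve(prof)
        with pytest.raises(ValueError, match="plateau"):
            find_unfolded_state(prof, f, threshold=0.1)

    def test_threshold_sensitivity(self):
        prof = _plateau_profile()
        f = force_curve(prof)
        r1, _ = find_unfolded_state(prof, f, threshold=0.1)
        r2, _ = find_unfolded_state(prof, f, threshold=0.05)
        assert 0 <= r1 - r2 <= 3.0  # moves left by at most the edge width


class TestDeltaG:
    def test_square_well_closed_form(self):
        """ΔG matches the analytic integral to 1e-6 kcal/mol."""
        W = 3.0
        r = np.linspace(5.0, 25.0, 2_000_001)
        omega = np.where((r >= 10.0) & (r <= 20.0), -W, 0.0)
        prof = FreeEnergyProfile(r, omega - omega.min())
        dg = delta_g_fold(prof, r_unfolded=24.0)
        vol = 4.0 * math.pi / 3.0 * (20.0 ** 3 - 10.0 ** 3)
        exact = -KT * math.log(
            (vol * math.exp(W / KT)
             + 4.0 * math.pi / 3.0 * (10.0 ** 3 - 5.0 ** 3)
             + 4.0 * math.pi / 3.0 * (24.0 ** 3 - 20.0 ** 3)) / 1660.0)
        assert dg == pytest.approx(exact, abs=1e-6)

    def test_zero_profile_reference_volume(self):
        """Δω ≡ 0 over a region of J-volume V_ref gives ΔG = 0."""
        r_hi = (3.0 * 1660.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        r = np.linspace(0.0, r_hi, 1_000_001)
        prof = FreeEnergyProfile(r, np.zeros_like(r))
        dg = delta_g_fold(prof, r_unfolded=r_hi)
        assert dg == pytest.approx(0.0, abs=1e-5)

    def test_additive_constant_invariance(self):
        prof = _plateau_profile()
        f = force_curve(prof)
        r_u, _ = find_unfolded_state(prof, f)
        dg1 = delta_g_fold(prof, r_u)
        shifted = FreeEnergyProfile(prof.r, prof.omega + 7.3)
        dg2 = delta_g_fold(shifted, r_u)
        assert dg1 == pytest.approx(dg2, abs=1e-10)

    def test_deeper_well_lowers_dg(self):
        r = np.arange(2, 60, 0.2)
        base = np.where((r > 8) & (r < 14), -2.0, 0.0)
        p1 = FreeEnergyProfile(r, base - base.min())
        deeper = np.where((r > 8) & (r < 14), -3.0, 0.0)
        p2 = FreeEnergyProfile(r, deeper - deeper.min())
        assert delta_g_fold(p2, 50.0) < delta_g_fold(p1, 50.0)

    def test_deep_well_limit(self):
        """ΔG → -W - kT ln(V_well/V_ref) as the well deepens."""
        W = 25.0
        r = np.linspace(5, 40, 200_001)
        omega = np.where((r >= 10) & (r <= 20), -W, 0.0)
        prof = FreeEnergyProfile(r, omega - omega.min())
        dg = delta_g_fold(prof, 39.0)
        v_well = 4 * math.pi / 3 * (20 ** 3 - 10 ** 3)
        assert dg == pytest.approx(-W - KT * math.log(v_well / 1660.0),
                                   abs=1e-3)

    def test_empty_folded_region(self):
        prof = _plateau_profile()
        with pytest.raises(ValueError, match="empty"):
            delta_g_fold(prof, r_unfolded=0.5)

    def test_unit_jacobian_flag(self):
        prof = _plateau_profile()
        dg_s = delta_g_fold(prof, 60.0, jacobian="spherical")
        dg_u = delta_g_fold(prof, 60.0, jacobian="unit")
        assert dg_u > dg_s  # unit measure integrates far less volume


class TestCorrelation:
    def test_identity_regression(self):
        vals = {"a": -3.0, "b": -7.5, "c": -12.0, "d": -1.0}
        rep = correlation_report(vals, vals)
        assert rep["r_squared"] == pytest.approx(1.0)
        assert rep["slope"] == pytest.approx(1.0)
        assert rep["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_labels_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            correlation_report({"a": 1, "b": 2, "c": 3},
                               {"a": 1, "b": 2, "d": 3})

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            correlation_report({"a": 1, "b": 2}, {"a": 1, "b": 2})

    def test_bundled_table_statistics(self):
        """Published 11-RNA set: simulation R²≈0.93 slope≈1.2;
        nearest-neighbor prediction R²≈0.96 slope≈1.5."""
        df = load_reference_table()
        assert len(df) == 11
        expt = dict(zip(df["label"], df["dg_expt"]))
        model = correlation_report(dict(zip(df["label"], df["dg_model"])), expt)
        mfold = correlation_report(dict(zip(df["label"], df["dg_mfold"])), expt)
        assert model["r_squared"] == pytest.approx(0.93, abs=0.005)
        assert model["slope"] == pytest.approx(1.2, abs=0.05)
        assert mfold["r_squared"] == pytest.approx(0.96, abs=0.01)
        assert mfold["slope"] == pytest.approx(1.5, abs=0.05)
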
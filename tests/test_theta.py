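"""Theta-phase extraction, phase tuning and precession statistics."""

from __future__ import annotations

import numpy as np
import pytest
from forageseq import placefields as pf
from forageseq import theta as th
from forageseq.core import BEHAVIOR_DT, BehaviorFrame


def straight_frame(n, speed=15.0, direction=0.0):
    t = np.arange(n) * BEHAVIOR_DT
    x = -40 + speed * BEHAVIOR_DT * np.arange(n)
    return BehaviorFrame(t, x, np.zeros(n), np.full(n, direction),
                         np.full(n, speed), np.ones(n, dtype=bool))


class TestPhaseExtraction:
    def test_pure_sinusoid_midpoint_phase(self):
        fs, f = 1000.0, 8.0
        t = np.arange(0, 20, 1 / fs)
        lfp = np.sin(2 * np.pi * f * t)
        frame = straight_frame(1900)
        series = th.extract_theta_phase(lfp, frame)
        # inter-peak midpoints have phase 180
        mids = (series.peaks[:-1] + series.peaks[1:]) / 2
        ph = series.phase_at(mids)
        np.testing.assert_allclose(ph[np.isfinite(ph)], 180.0, atol=1.0)
        # interior peaks are 1/f apart (filter edges distort the ends)
        np.testing.assert_allclose(np.diff(series.peaks[3:-3]), 1 / f, atol=1e-3)

    def test_sequential_refractory_scan(self):
        cand = np.array([0.0, 0.050, 0.100, 0.150])
        kept = th.retain_peaks(cand, refractory=0.06)
        np.testing.assert_allclose(kept, [0.0, 0.100])

    def test_phase_zero_at_peaks_and_monotone(self):
        peaks = np.array([0.0, 0.12, 0.25, 0.37])
        t = np.arange(0, 0.37, 0.001)
        ph = th.phase_between_peaks(t, peaks)
        ok = np.isfinite(ph)
        assert np.all(ph[ok] >= 0) and np.all(ph[ok] < 360)
        for p in peaks[:-1]:
            assert ph[np.argmin(np.abs(t - p))] == pytest.approx(0.0, abs=4.0)
        # strictly increasing within each inter-peak interval
        seg = ph[(t >= 0.0) & (t < 0.12)]
        assert np.all(np.diff(seg) > 0)

    def test_too_few_peaks_all_nan(self):
        frame = straight_frame(500)
        ph = th.phase_between_peaks(frame.t, np.array([1.0]))
        assert np.isnan(ph).all()


class TestPhaseTuning:
    def test_exact_cosine_curve_index_one(self):
        centers = (np.arange(18) + 0.5) * 20.0
        rate = 1.0 + np.cos(np.radians(centers))
        amp, phi0, mean = th.fit_sinusoid(rate)
        assert amp == pytest.approx(1.0, abs=1e-9)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert th.modulation_index_of(rate) == pytest.approx(1.0, abs=1e-9)
        assert phi0 == pytest.approx(0.0, abs=1e-6) or phi0 == pytest.approx(360, abs=1e-6)

    def test_modulation_depth_recovery_with_smoothing_attenuation(self, sim_bundle):
        # the generator's depth-m cosine gain must be recovered as
        # m*exp(-sigma^2/2) after the 20-deg circular Gaussian smoothing
        rng = np.random.default_rng(0)
        n = 200_000
        frame = straight_frame(n)
        phase = rng.uniform(0, 360, n)
        m = 0.6
        lam = 5.0 * (1 + m * np.cos(np.radians(phase - 120.0))) * BEHAVIOR_DT
        counts = rng.poisson(lam)
        spike_idx = np.repeat(np.arange(n), counts)
        series = th.ThetaPhaseSeries(
            peaks=np.array([]), phase=phase, coverage=np.ones(n, dtype=bool)
        )
        rate = th._phase_bin_rate(phase[spike_idx], phase)
        idx = th.modulation_index_of(rate)
        sigma = np.radians(20)
        assert idx == pytest.approx(m * np.exp(-sigma**2 / 2), abs=0.05)

    def test_flat_cell_rarely_significant(self, sim_bundle):
        frame = sim_bundle["frame"]
        phase = th.extract_theta_phase(sim_bundle["session"].lfp, frame)
        tuning = th.phase_tuning(
            sim_bundle["session"].spikes["flat"], phase, frame,
            rng=np.random.default_rng(1),
        )
        assert not tuning.sig_modulation
        assert tuning.modulation_index < 0.15

    def test_theta_cell_significant(self, sim_bundle):
        frame = sim_bundle["frame"]
        phase = th.extract_theta_phase(sim_bundle["session"].lfp, frame)
        tuning = th.phase_tuning(
            sim_bundle["session"].spikes["place"], phase, frame,
            rng=np.random.default_rng(2),
        )
        assert tuning.sig_modulation
        # generator depth 0.5, smoothing attenuation ~0.94
        assert tuning.modulation_index == pytest.approx(0.47, abs=0.1)

    def test_too_few_spikes_not_significant(self, sim_bundle):
        frame = sim_bundle["frame"]
        phase = th.extract_theta_phase(sim_bundle["session"].lfp, frame)
        tuning = th.phase_tuning(
            sim_bundle["session"].spikes["place"][:20], phase, frame,
            rng=np.random.default_rng(3),
        )
        assert not tuning.sig_modulation


class TestFieldBoundary:
    def test_largest_subfield_selected(self):
        rate = np.full((20, 20), np.nan)
        valid = np.zeros((20, 20), bool)
        valid[2:18, 2:18] = True
        rate[valid] = 1.0
        # two disjoint fields: 10 bins and 4 bins
        rate[3:8, 3:5] = 10.0
        rate[14:16, 14:16] = 10.0
        rmap = pf.RateMap(rate, valid, np.ones((20, 20)), 100)
        ens = pf.ShuffleEnsemble(
            strengths=np.zeros(10),
            percentile95=np.where(valid, 5.0, np.nan),
            maps=np.zeros((1, 20, 20)),
        )
        fb = th.field_boundary(rmap, ens)
        assert fb is not None
        assert fb.significant.sum() == 10
        assert fb.significant[3:8, 3:5].all()

    def test_no_significant_bins_returns_none(self):
        valid = np.ones((20, 20), bool)
        rmap = pf.RateMap(np.ones((20, 20)), valid, np.ones((20, 20)), 10)
        ens = pf.ShuffleEnsemble(
            strengths=np.zeros(10), percentile95=np.full((20, 20), 5.0),
            maps=np.zeros((1, 20, 20)),
        )
        assert th.field_boundary(rmap, ens) is None

    def test_single_field_contains_true_center(self, sim_bundle):
        frame = sim_bundle["frame"]
        vb = sim_bundle["valid_bins"]
        spikes = sim_bundle["session"].spikes["place"]
        rng = np.random.default_rng(4)
        rmap = pf.estimate_rate_map(frame, spikes, valid_bins=vb)
        ens = pf.shuffle_ensemble(frame, spikes, vb, rng=rng)
        fb = th.field_boundary(rmap, ens)
        assert fb is not None
        assert fb.contains(np.array([10.0]), np.array([5.0]))[0]
        assert np.hypot(fb.com[0] - 10, fb.com[1] - 5) < 7.5


def square_boundary(half=10.0, com=(0.0, 0.0)):
    hull = np.array(
        [[com[0] - half, com[1] - half], [com[0] + half, com[1] - half],
         [com[0] + half, com[1] + half], [com[0] - half, com[1] + half]]
    )
    sig = np.zeros((20, 20), bool)
    return th.FieldBoundary(significant=sig, hull=hull, com=com)


class TestPdcd:
    def test_zero_at_com(self):
        fb = square_boundary()
        d = th.pdcd_of(np.array([0.0]), np.array([0.0]), np.array([30.0]), fb)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_chord_run_monotone_minus_one_to_plus_one(self):
        fb = square_boundary(half=10.0)
        x = np.linspace(-9.99, 9.99, 50)
        d = th.pdcd_of(x, np.zeros(50), np.zeros(50), fb)
        assert np.all(np.diff(d) > 0)
        assert d[0] == pytest.approx(-1.0, abs=0.01)
        assert d[-1] == pytest.approx(1.0, abs=0.01)

    def test_reversed_direction_flips_sign(self):
        fb = square_boundary()
        d_fwd = th.pdcd_of(np.array([5.0]), np.array([0.0]), np.array([0.0]), fb)
        d_bwd = th.pdcd_of(np.array([5.0]), np.array([0.0]), np.array([180.0]), fb)
        assert d_fwd[0] == pytest.approx(-d_bwd[0])
        assert d_fwd[0] > 0

    def test_undefined_direction_dropped(self):
        fb = square_boundary()
        frame = straight_frame(100)
        frame.direction[:] = np.nan
        d, spk = th.compute_pdcd(frame, fb, frame.t[10:12])
        assert d.size == 0


class TestCircularLinearFit:
    def test_exact_linear_phase_model(self):
        d = np.linspace(-1, 1, 200)
        phases = (360.0 - 180.0 * d) % 360.0
        s, rho = th.circular_linear_fit(phases, d)
        assert s == pytest.approx(-0.5, abs=0.01)
        assert abs(rho) == pytest.approx(1.0, abs=1e-6)

    def test_constant_distance_degenerate(self):
        d = np.zeros(50)
        phases = np.random.default_rng(0).uniform(0, 360, 50)
        s, rho = th.circular_linear_fit(phases, d)
        assert np.isnan(rho)

    def test_rho_invariant_to_phase_rotation(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(-1, 1, 300)
        phases = (100 - 120 * d + rng.normal(0, 30, 300)) % 360
        s1, rho1 = th.circular_linear_fit(phases, d)
        s2, rho2 = th.circular_linear_fit((phases + 77) % 360, d)
        assert rho1 == pytest.approx(rho2, abs=1e-6)
        assert s1 == pytest.approx(s2, abs=1e-6)


class TestPrecessionTest:
    def test_p_value_identities(self):
        # z = 0 -> p = 1; |z| = 1.96 -> p ~ 0.05
        from scipy.special import erf

        assert 1 - erf(0.0) == 1.0
        assert 1 - erf(1.96 / np.sqrt(2)) == pytest.approx(0.0500, abs=5e-4)

    def test_null_phases_give_large_p(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(-1, 1, 100)
        phases = rng.uniform(0, 360, 100)
        ps = [
            th.precession_test(rng.uniform(0, 360, 100), rng.uniform(-1, 1, 100)).p
            for _ in range(50)
        ]
        assert np.mean(np.array(ps) < 0.025) <= 0.1

    def test_labeled_simulation_detection(self):
        rng = np.random.default_rng(3)
        hits, fps = 0, 0
        n_cells = 40
        for _ in range(n_cells):
            d = rng.uniform(-1, 1, 200)
            phases = (180 - 180 * d + rng.normal(0, 40, 200)) % 360
            if th.precession_test(phases, d).significant:
                hits += 1
            null = rng.uniform(0, 360, 200)
            if th.precession_test(null, d).significant:
                fps += 1
        assert hits / n_cells >= 0.9
        assert fps / n_cells <= 0.05 + 0.05  # binomial slack at n = 40

    def test_coverage_and_count_gates(self):
        rng = np.random.default_rng(4)
        # strong precession but too few spikes
        d = rng.uniform(-1, 1, 20)
        phases = (180 - 180 * d) % 360
        res = th.precession_test(phases, d)
        assert not res.significant
        # narrow pdcd range -> coverage below 45 deg
        d = rng.uniform(-0.05, 0.05, 200)
        phases = (180 - 180 * d + rng.normal(0, 5, 200)) % 360
        res = th.precession_test(phases, d)
        assert res.phase_coverage <= 45 or not res.significant

    def test_generator_precessing_cell_detected(self, sim_bundle):
        frame = sim_bundle["frame"]
        vb = sim_bundle["valid_bins"]
        spikes = sim_bundle["session"].spikes["prec"]
        rng = np.random.default_rng(5)
        rmap = pf.estimate_rate_map(frame, spikes, valid_bins=vb)
        ens = pf.shuffle_ensemble(frame, spikes, vb, rng=rng)
        fb = th.field_boundary(rmap, ens)
        d, spk = th.compute_pdcd(frame, fb, spikes)
        phase = th.extract_theta_phase(sim_bundle["session"].lfp, frame)
        ph = phase.phase_at(spk)
        ok = np.isfinite(ph)
        res = th.precession_test(ph[ok], d[ok])
        assert res.significant
        assert res.slope < 0


class TestCleanRuns:
    def test_straight_fast_chord_retained(self):
        fb = square_boundary(half=10.0)
        frame = straight_frame(600, speed=15.0)
        runs = th.select_clean_runs(frame, fb)
        assert len(runs) == 1
        a, b = runs[0]
        assert frame.x[a] < -9 and frame.x[b - 1] > 9

    def test_pause_inside_field_rejected(self):
        fb = square_boundary(half=10.0)
        frame = straight_frame(600, speed=15.0)
        mid = np.argmin(np.abs(frame.x))
        frame.speed[mid - 5 : mid + 5] = 2.0
        assert th.select_clean_runs(frame, fb) == []

    def test_field_clipping_run_rejected(self):
        # a run that only clips the far half of the field never comes
        # closer than |pdcd| = 0.5 to the center and must be rejected
        fb = square_boundary(half=10.0)
        n = 400
        t = np.arange(n) * BEHAVIOR_DT
        x = 5.0 + 15 * BEHAVIOR_DT * np.arange(n)  # starts mid-field at x=5
        frame = BehaviorFrame(t, x, np.zeros(n), np.zeros(n),
                              np.full(n, 15.0), np.ones(n, dtype=bool))
        assert th.select_clean_runs(frame, fb) == []
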
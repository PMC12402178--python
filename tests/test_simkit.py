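"""Simulator statistical laws: waiting times, dwell laws, rendering physics."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from crosskymo import simkit
from crosskymo.datatypes import ParticleTrack


class TestDynamicInstability:
    def test_no_catastrophe_deterministic_growth(self):
        p = simkit.DynamicsParams(f_cat=0.0, v_growth=2.0, duration=300.0, rng_seed=0)
        traj, phases, transitions = simkit.simulate_dynamic_instability(p)
        assert len(phases) == 1
        assert transitions == []
        assert traj.tip_positions[-1] - p.seed_length == pytest.approx(10.0)

    def test_growth_phase_durations_exponential_mean(self):
        """f_cat = 0.01 → mean growth-phase duration 100 s within 3 SE."""
        durations = []
        for s in range(60):
            p = simkit.DynamicsParams(f_cat=0.01, f_res=0.2, v_shrink=60.0,
                                      duration=3000.0, rng_seed=700 + s)
            _, phases, transitions = simkit.simulate_dynamic_instability(p)
            cat_times = {t for t, k in transitions if k == "catastrophe"}
            # only phases terminated by a catastrophe are complete exponential draws
            durations += [ph.duration for ph in phases
                          if ph.kind == "growth" and ph.t_end in cat_times]
        d = np.array(durations)
        se = d.std(ddof=1) / math.sqrt(d.size)
        assert abs(d.mean() - 100.0) <= 3 * se

    def test_two_state_stationary_fraction(self):
        """Fraction of time growing → f_res/(f_cat+f_res) = 0.909 (Markov oracle).

        Positive net drift (v_growth/f_cat >> v_shrink/f_res) keeps the tip
        clear of the seed so the unbounded two-state result applies.
        """
        tot_growth = tot = 0.0
        for s in range(20):
            p = simkit.DynamicsParams(v_growth=3.0, v_shrink=6.0, f_cat=0.005,
                                      f_res=0.05, duration=10_000.0, rng_seed=200 + s)
            _, phases, _ = simkit.simulate_dynamic_instability(p)
            tot_growth += sum(x.duration for x in phases if x.kind == "growth")
            tot += p.duration
        assert tot_growth / tot == pytest.approx(0.05 / 0.055, abs=0.015)

    def test_length_never_below_seed(self):
        p = simkit.DynamicsParams(f_cat=0.05, f_res=0.01, duration=2000.0, rng_seed=9)
        traj, _, transitions = simkit.simulate_dynamic_instability(p)
        assert np.all(traj.tip_positions >= p.seed_length - 1e-12)
        assert any(k == "seed_regrowth" for _, k in transitions)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            simkit.DynamicsParams(v_growth=float("nan"))
        with pytest.raises(ValueError):
            simkit.DynamicsParams(f_cat=-0.1)
        with pytest.raises(ValueError):
            simkit.DynamicsParams(duration=0.0)

    def test_reproducible_given_seed(self):
        p = simkit.DynamicsParams(rng_seed=5)
        t1, ph1, tr1 = simkit.simulate_dynamic_instability(p)
        t2, ph2, tr2 = simkit.simulate_dynamic_instability(p)
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.tip_positions, t2.tip_positions)
        assert tr1 == tr2

    def test_phase_log_partitions_duration(self):
        p = simkit.DynamicsParams(f_cat=0.01, f_res=0.05, duration=900.0, rng_seed=11)
        _, phases, _ = simkit.simulate_dynamic_instability(p)
        assert phases[0].t_start == 0.0
        assert phases[-1].t_end == pytest.approx(900.0)
        for a, b in zip(phases[:-1], phases[1:]):
            assert b.t_start == pytest.approx(a.t_end)


@pytest.fixture(scope="module")
def homogeneous_dwells():
    params = simkit.BinderParams(k_on=0.17, k_off_gdp=0.1, k_off_seed=0.1,
                                 diffusion_coeff=0.02, rng_seed=3)
    lattice = simkit.StaticLattice(length=10.0, seed_end=0.0)
    tracks = simkit.simulate_binder_tracks(params, lattice, duration=6000.0,
                                           frame_interval=0.25)
    # completed dwells only: drop tracks censored by the movie end
    return np.array([t.t_off - t.t_on for t in tracks if t.t_off < 6000.0 - 0.125])


class TestBinderTracks:

    def test_dwell_median_matches_exponential(self, homogeneous_dwells):
        assert homogeneous_dwells.size > 9000
        med = np.median(homogeneous_dwells)
        assert med == pytest.approx(math.log(2) / 0.1, rel=0.02)

    def test_dwell_distribution_ks_exponential(self, homogeneous_dwells):
        """KS test against Exp(0.1) at alpha = 0.01 (seeded, so no false positive)."""
        stat, p = sps.kstest(homogeneous_dwells, "expon", args=(0, 10.0))
        assert p > 0.01

    def test_zero_diffusion_constant_positions(self):
        params = simkit.BinderParams(k_on=0.5, diffusion_coeff=0.0, rng_seed=4)
        tracks = simkit.simulate_binder_tracks(params, simkit.StaticLattice(5.0), 100.0)
        assert tracks
        for tr in tracks:
            assert np.all(tr.positions == tr.positions[0])

    def test_seed_occupancy_higher_than_lattice(self):
        """Slower seed off-rate → higher time-averaged density on the seed,
        with the ratio of mean dwell times as the oracle."""
        params = simkit.BinderParams(k_on=1.0, k_off_gdp=1.0, k_off_seed=0.2,
                                     diffusion_coeff=0.0, rng_seed=4)
        lat = simkit.StaticLattice(length=10.0, seed_end=5.0)
        tracks = simkit.simulate_binder_tracks(params, lat, duration=400.0)
        occ_seed = sum(t.t_off - t.t_on for t in tracks if t.positions[0] <= 5.0)
        occ_gdp = sum(t.t_off - t.t_on for t in tracks if t.positions[0] > 5.0)
        ratio = occ_seed / occ_gdp
        # equal landing flux on equal lengths; dwell ratio = k_gdp/k_seed = 5
        assert ratio == pytest.approx(5.0, rel=0.25)

    def test_zero_length_lattice_warns_empty(self):
        params = simkit.BinderParams(rng_seed=0)
        with pytest.warns(UserWarning, match="zero-length"):
            tracks = simkit.simulate_binder_tracks(params, simkit.StaticLattice(0.0), 10.0)
        assert tracks == []

    def test_intensity_multiples_from_weights(self):
        params = simkit.BinderParams(k_on=1.0, oligomer_weights={1: 0.5, 3: 0.5}, rng_seed=6)
        tracks = simkit.simulate_binder_tracks(params, simkit.StaticLattice(10.0), 200.0)
        mults = {t.intensities[0] for t in tracks}
        assert mults <= {1.0, 3.0}
        assert len(mults) == 2


class TestFrapTraceSim:
    def test_noiseless_equals_closed_form(self):
        tr = simkit.simulate_frap_trace(0.5, plateau=0.8, noise_sigma=0.0)
        pre = tr.intensities[: tr.bleach_index]
        np.testing.assert_allclose(pre, 1.0)
        t_post = tr.times[tr.bleach_index:] - tr.times[tr.bleach_index]
        np.testing.assert_allclose(tr.intensities[tr.bleach_index:],
                                   0.8 * (1 - np.exp(-0.5 * t_post)), atol=1e-14)

    def test_bleach_frame_timing(self):
        tr = simkit.simulate_frap_trace(0.3, frame_interval=0.2, n_prebleach=55)
        assert tr.times[tr.bleach_index] == pytest.approx(11.0)
        assert tr.bleach_index == 55

    def test_negative_koff_rejected(self):
        with pytest.raises(ValueError):
            simkit.simulate_frap_trace(-0.5)


class TestCrosslinkEvents:
    def test_sliding_track_moves_at_requested_speed(self):
        mt, _, _ = simkit.simulate_dynamic_instability(simkit.DynamicsParams(rng_seed=1))
        tracks, recs = simkit.simulate_crosslink_events(
            [{"label": "sliding", "slide_speed": 0.1, "n_frames": 12}], mt,
            frame_interval=2.0, rng_seed=0, jitter_px=0.0,
        )
        actin = next(t for t in tracks if t.channel == "actin")
        disp = np.diff(actin.positions)
        np.testing.assert_allclose(disp, 0.2, atol=1e-9)  # 0.1 µm/s × 2 s

    def test_tip_tracking_track_follows_tip(self):
        mt, _, _ = simkit.simulate_dynamic_instability(simkit.DynamicsParams(rng_seed=1))
        tracks, _ = simkit.simulate_crosslink_events(
            [{"label": "tip_tracking", "n_frames": 10}], mt, rng_seed=0, jitter_px=0.0,
        )
        actin = next(t for t in tracks if t.channel == "actin")
        np.testing.assert_allclose(actin.positions, mt.tip_at(actin.times), atol=0.16)

    def test_unknown_label_rejected(self):
        mt, _, _ = simkit.simulate_dynamic_instability(simkit.DynamicsParams(rng_seed=1))
        with pytest.raises(ValueError, match="label"):
            simkit.simulate_crosslink_events([{"label": "zippering"}], mt)


class TestRenderer:
    def test_no_emitters_constant_background(self):
        optics = simkit.OpticsParams(noise_model="none", background_level=7.0)
        truth = simkit.GroundTruth()
        k = simkit.render_kymograph(truth, optics, duration=10.0, n_positions=30)
        assert np.all(k.data == 7.0)

    def test_static_emitter_gaussian_ridge(self):
        optics = simkit.OpticsParams(pixel_size=1.0, frame_interval=1.0, psf_sigma=1.5,
                                     photons_per_fluor=100.0, background_level=0.0,
                                     noise_model="none")
        n = 10
        tr = ParticleTrack("e", np.arange(n, dtype=float), np.full(n, 12.0),
                           np.ones(n), channel="binder")
        k = simkit.render_kymograph(simkit.GroundTruth(tracks=[tr]), optics,
                                    duration=n - 1.0, n_positions=30)
        rows = k.data[:-1]  # last frame midpoint falls past the dwell
        peaks = rows.argmax(axis=1)
        assert np.all(peaks == 12)
        # each row equals the same Gaussian profile
        np.testing.assert_allclose(rows, np.tile(rows[0], (rows.shape[0], 1)), rtol=1e-12)

    def test_rendering_conservation(self):
        """Noise off: total intensity above background = emitters × photons × mass."""
        optics = simkit.OpticsParams(pixel_size=1.0, frame_interval=1.0, psf_sigma=1.2,
                                     photons_per_fluor=150.0, background_level=5.0,
                                     noise_model="none")
        n = 20
        tracks = [
            ParticleTrack(f"e{i}", np.arange(n, dtype=float),
                          np.full(n, 10.0 + 5 * i), np.ones(n), channel="binder")
            for i in range(3)
        ]
        k = simkit.render_kymograph(simkit.GroundTruth(tracks=tracks), optics,
                                    duration=n - 1.0, n_positions=40)
        above = (k.data - 5.0).sum()
        expected = 3 * (n - 1) * 150.0  # n-1 frame midpoints inside each dwell
        assert above == pytest.approx(expected, rel=0.01)

    def test_moving_emitter_slope_recovered(self):
        optics = simkit.OpticsParams(pixel_size=1.0, frame_interval=1.0, psf_sigma=1.2,
                                     photons_per_fluor=100.0, background_level=5.0,
                                     noise_model="none")
        n = 30
        times = np.arange(n, dtype=float)
        tr = ParticleTrack("e", times, 5.0 + times, np.ones(n), channel="binder")
        k = simkit.render_kymograph(simkit.GroundTruth(tracks=[tr]), optics,
                                    duration=n - 1.0, n_positions=50)
        sig = k.data - 5.0
        rows = np.nonzero(sig.sum(axis=1) > 1.0)[0]
        centroid = (sig[rows] * np.arange(50)).sum(axis=1) / sig[rows].sum(axis=1)
        slope = np.polyfit(rows.astype(float), centroid, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.05)

    def test_deterministic_given_seed(self):
        optics = simkit.OpticsParams()
        p = simkit.DynamicsParams(rng_seed=2)
        traj, _, _ = simkit.simulate_dynamic_instability(p)
        truth = simkit.GroundTruth(trajectory=traj)
        k1 = simkit.render_kymograph(truth, optics, channel="microtubule", rng_seed=42)
        k2 = simkit.render_kymograph(truth, optics, channel="microtubule", rng_seed=42)
        np.testing.assert_array_equal(k1.data, k2.data)
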
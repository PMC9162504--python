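"""Monte Carlo kernel: scattering, boundaries, kinematics, conservation."""

import math

import numpy as np
import pytest

from slabmc.optics_utils import PulseSpec
from slabmc.sources import BeamSpec
from slabmc.transport import (
    C_UM_PS,
    EXIT_TRANSMIT,
    SlabSpec,
    fresnel_interaction,
    fresnel_reflectance,
    henyey_greenstein_scatter,
    propagate_batch,
    propagate_photon,
    run_simulation,
)
from slabmc.detectors import energy_balance

DELTA = PulseSpec("delta", 1.0)
PENCIL = BeamSpec("pencil")


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.165, 0.8])
    def test_mean_cosine_equals_g(self, g):
        rng = np.random.default_rng(1)
        u0 = np.array([0.0, 0.0, 1.0])
        n = 200_000
        xi = rng.random((n, 2))
        cos = np.empty(n)
        for i in range(n):
            cos[i] = henyey_greenstein_scatter(u0, g, xi[i, 0], xi[i, 1])[2]
        # ⟨cosθ⟩ = g; std of cosθ is ≤ 0.6 so 4·SE ≈ 5e-3 at this n
        assert cos.mean() == pytest.approx(g, abs=5e-3)

    def test_output_unit_norm(self):
        rng = np.random.default_rng(2)
        u = np.array([0.3, -0.4, math.sqrt(1 - 0.25)])
        for _ in range(200):
            out = henyey_greenstein_scatter(u, 0.165, rng.random(), rng.random())
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12
            u = out


class TestFresnel:
    def test_normal_incidence_reflectance(self):
        assert fresnel_reflectance(1.0, 1.0, 1.526) == pytest.approx(
            ((1 - 1.526) / (1 + 1.526)) ** 2, rel=1e-12)

    def test_total_internal_reflection(self):
        # internal angle beyond arcsin(1/1.526) ≈ 40.9°
        u = np.array([math.sin(math.radians(50)), 0.0, math.cos(math.radians(50))])
        for xi in (0.0, 0.5, 0.999):
            out, transmitted = fresnel_interaction(u, 1.526, 1.0, xi)
            assert not transmitted
            assert out[2] == pytest.approx(-u[2])

    def test_matched_interface_passes_unchanged(self):
        u = np.array([0.6, 0.0, 0.8])
        out, transmitted = fresnel_interaction(u, 1.5, 1.5, 0.999999)
        assert transmitted
        np.testing.assert_allclose(out, u, atol=1e-15)

    def test_snell_refraction_angle(self):
        u = np.array([math.sin(0.3), 0.0, math.cos(0.3)])
        out, transmitted = fresnel_interaction(u, 1.0, 1.526, 0.999999)
        assert transmitted
        assert math.asin(out[0]) == pytest.approx(math.asin(math.sin(0.3) / 1.526), rel=1e-9)


class TestBallistic:
    def test_clear_slab_transit_and_replica(self):
        # scattering-free 164-μm slab, n = 1.509: transit 0.825 ps, first
        # internally reflected replica lags by 2·L·n/c = 1.651 ps
        slab = SlabSpec(164.0, 1.509, mu_s=0.0, mu_a=0.0)
        rec = run_simulation(DELTA, PENCIL, slab, 200_000, 17)
        tr = rec.transmitted
        transit = 164.0 * 1.509 / C_UM_PS
        times = np.unique(np.round(tr.time, 9))
        assert times[0] == pytest.approx(transit, abs=1e-9)
        assert times[1] - times[0] == pytest.approx(2 * transit, abs=1e-9)
        # replica weight ratio is R² at each double bounce
        R = fresnel_reflectance(1.0, 1.509, 1.0)
        w_main = tr.weight[np.isclose(tr.time, times[0])].sum()
        w_rep = tr.weight[np.isclose(tr.time, times[1])].sum()
        assert w_rep / w_main == pytest.approx(R**2, rel=0.15)

    def test_unscattered_fraction_beer_lambert(self):
        # ballistic transmission = T_Fresnel² · exp(−(μs+μa)·L)
        slab = SlabSpec(164.0, 1.509, mu_s=0.01, mu_a=1e-4)
        n = 400_000
        rec = run_simulation(DELTA, PENCIL, slab, n, 23)
        tr = rec.transmitted
        ball = tr.weight[tr.scatter_count == 0]
        # unscattered photons that exited straight through (no internal bounce)
        direct = ball[np.isclose(tr.time[tr.scatter_count == 0],
                                 164.0 * 1.509 / C_UM_PS, atol=1e-9)]
        R = fresnel_reflectance(1.0, 1.0, 1.509)
        expected = (1 - R) ** 2 * math.exp(-(0.01 + 1e-4) * 164.0)
        measured = direct.sum() / n
        sigma = math.sqrt(expected * (1 - expected) / n)
        assert abs(measured - expected) < 4 * sigma


class TestConservation:
    @pytest.mark.parametrize("fixture_name", ["clear_slab", "membrane"])
    def test_energy_balance_sums_to_one(self, fixture_name):
        from slabmc.interface import generate_fixtures

        cfg = generate_fixtures(fixture_name)
        rec = run_simulation(cfg.pulse, cfg.beam, cfg.slab, 50_000, 31,
                             time_cap=cfg.time_cap_ps)
        bal = energy_balance(rec, 50_000.0)  # raises beyond 1e-10 imbalance
        assert bal["T_total"] + bal["R_total"] + bal["A_total"] + bal["truncated"] == pytest.approx(1.0, abs=1e-10)

    def test_same_seed_bit_identical(self):
        slab = SlabSpec(164.0, 1.526, mu_s=0.03, g=0.165, mu_a=4.5e-5)
        a = run_simulation(DELTA, PENCIL, slab, 20_000, 99)
        b = run_simulation(DELTA, PENCIL, slab, 20_000, 99)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.weight, b.weight)

    def test_zero_photons_empty(self):
        slab = SlabSpec(164.0, 1.526, mu_s=0.03)
        rec = run_simulation(DELTA, PENCIL, slab, 0, 1)
        assert rec.code.size == 0


class TestDiffusionLimit:
    def test_decay_matches_fundamental_eigenvalue(self, thick_run):
        from slabmc.analysis import fit_decay_rate

        cfg, rec, det = thick_run
        slab = cfg.slab
        D = slab.energy_velocity * slab.transport_mfp / 3
        ze = 2 * slab.transport_mfp / 3  # index-matched extrapolation length
        tau1 = (slab.thickness + 2 * ze) ** 2 / (math.pi**2 * D)
        fit = fit_decay_rate(det.histogram_t, cfg.decay_window_ps)
        assert fit.value == pytest.approx(tau1, rel=0.05)


class TestInvariances:
    @pytest.mark.parametrize("mu_s", [0.001, 0.01, 0.1])
    def test_lambertian_mean_pathlength_is_2L(self, mu_s):
        # mean pathlength invariance: ⟨s⟩ = 2L for Lambertian illumination of
        # an index-matched non-absorbing slab, independent of μs
        L = 164.0
        slab = SlabSpec(L, 1.526, n_front=1.526, n_back=1.526, mu_s=mu_s, mu_a=0.0)
        n = 150_000
        rng = np.random.default_rng(61)
        mu_z = np.sqrt(rng.random(n))  # Lambertian: p(μ) ∝ μ
        phi = 2 * np.pi * rng.random(n)
        st = np.sqrt(1 - mu_z**2)
        dirs = np.stack([st * np.cos(phi), st * np.sin(phi), mu_z], axis=1)
        origins = np.zeros((n, 3))
        rec = propagate_batch(origins, dirs, np.zeros(n), slab, seed=71,
                              time_cap=2000.0, apply_entry_fresnel=False)
        assert rec.path.mean() == pytest.approx(2 * L, rel=0.02)

    def test_similarity_relation_late_decay(self):
        # (μs, g) and (μs(1−g), 0) share the late-time transmittance decay
        from slabmc.analysis import fit_decay_rate
        from slabmc.detectors import DetectorSet

        taus = []
        for mu_s, g in [(1 / 34.402, 0.165), (1 / 41.2, 0.0)]:
            slab = SlabSpec(164.0, 1.526, mu_s=mu_s, g=g, mu_a=0.0)
            rec = run_simulation(DELTA, PENCIL, slab, 600_000, 81)
            det = DetectorSet.default()
            det.accumulate(rec)
            taus.append(fit_decay_rate(det.histogram_t, (3.0, 9.0)))
        diff = abs(taus[0].value - taus[1].value)
        bound = 3 * math.hypot(taus[0].error, taus[1].error) + 0.03 * taus[1].value
        assert diff < bound


class TestSinglePhoton:
    def test_clear_matched_slab_exit_time(self):
        slab = SlabSpec(100.0, 1.5, n_front=1.5, n_back=1.5, mu_s=0.0)
        rec = propagate_photon([0, 0, 0], [0, 0, 1], 0.0, slab)
        assert rec.code[0] == EXIT_TRANSMIT
        assert rec.time[0] == pytest.approx(100.0 * 1.5 / C_UM_PS, rel=1e-12)
        assert rec.path[0] == pytest.approx(100.0, rel=1e-12)

    def test_time_cap_truncates_and_reports(self):
        slab = SlabSpec(164.0, 1.526, mu_s=0.1, g=0.0)
        rec = run_simulation(DELTA, PENCIL, slab, 5000, 3, time_cap=0.5)
        assert np.any(rec.code == 3)
        bal = energy_balance(rec, 5000.0)
        assert bal["truncated"] > 0
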
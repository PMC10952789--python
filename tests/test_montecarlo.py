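"""Random-walk engine: steps, transits, reflections, and signals."""

import numpy as np
import pytest

from myowalk.montecarlo import (
    WalkConfig,
    advance_with_membranes,
    propose_step,
    run_diffusion,
    run_walk,
    seed_walkers,
    transit_probability,
)
from myowalk.sequences import SequenceSpec, default_spec, make_waveform
from myowalk.substrate import ECS


class TestProposeStep:
    def test_component_magnitudes_exact(self):
        rng = np.random.default_rng(0)
        d = propose_step(rng, D_local=1.0, dt=0.01, n=500)
        assert np.allclose(np.abs(d), np.sqrt(0.02))

    def test_mean_square_displacement(self):
        rng = np.random.default_rng(1)
        n = 200_000
        d = propose_step(rng, D_local=2.5, dt=0.1, n=n)
        # per component: exactly 2 D dt (fixed magnitude), mean ~ 0
        assert np.allclose((d**2).mean(axis=0), 2 * 2.5 * 0.1)
        se = np.sqrt(2 * 2.5 * 0.1) / np.sqrt(n)
        assert np.all(np.abs(d.mean(axis=0)) < 3 * se)


class TestTransitProbability:
    def test_impermeable_is_zero(self):
        assert transit_probability(0.0, 0.5, 1.0, 2.5, ecs_to_ics=False) == 0.0

    def test_high_permeability_limit(self):
        p = transit_probability(1e9, 0.5, 1.0, 2.5, ecs_to_ics=False)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_formula_value(self):
        # p_b = 2*0.01*0.5 / (1 + 2*0.01*0.5) = 0.01/1.01
        p = transit_probability(0.01, 0.5, 1.0, 2.5, ecs_to_ics=False)
        assert p == pytest.approx(0.01 / 1.01, rel=1e-12)

    def test_diffusivity_step_factor_on_entry(self):
        pb = transit_probability(0.01, 0.5, 1.0, 2.5, ecs_to_ics=False)
        pin = transit_probability(0.01, 0.5, 1.0, 2.5, ecs_to_ics=True, pd_exponent=1.0)
        assert pin == pytest.approx(pb * (1.0 / 2.5), rel=1e-12)


class TestAdvance:
    def test_free_path_is_exact(self, square_cell_substrate, ):
        cfg = WalkConfig(n_walkers=1, n_steps=1)
        p, c, ov = advance_with_membranes(
            square_cell_substrate, cfg, (20.0, 20.0, 50.0), 0, (1.0, 1.0, 1.0)
        )
        assert np.allclose(p, (21.0, 21.0, 51.0))
        assert c == 0 and not ov

    def test_impermeable_wall_reflects_to_mirror_image(self, square_cell_substrate):
        """kappa = 0: the endpoint is the mirror image about the wall plane."""
        cfg = WalkConfig(n_walkers=1, n_steps=1, kappa_sarco=0.0)
        start = np.array([28.0, 20.0, 50.0])
        disp = np.array([4.0, 1.0, 0.5])  # would end at x=32, wall at x=30
        p, c, ov = advance_with_membranes(square_cell_substrate, cfg, start, 0, disp)
        unimpeded = start + disp
        mirror = unimpeded.copy()
        mirror[0] = 2 * 30.0 - unimpeded[0]
        assert np.allclose(p, mirror, atol=1e-5)
        assert c == 0

    def test_certain_transit_preserves_step_when_d_equal(self, square_cell_substrate):
        """kappa -> inf with D_ICS = D_ECS: straight-through crossing."""
        cfg = WalkConfig(n_walkers=1, n_steps=1, kappa_sarco=1e9, D_ics=2.5, D_ecs=2.5)
        start = np.array([28.0, 20.0, 50.0])
        disp = np.array([4.0, 0.0, 0.0])
        p, c, ov = advance_with_membranes(square_cell_substrate, cfg, start, 0, disp)
        assert np.allclose(p, start + disp, atol=1e-5)
        assert c == ECS

    def test_crossing_rescales_remaining_length(self, square_cell_substrate):
        """ICS -> ECS with D_ECS > D_ICS stretches the remaining segment."""
        cfg = WalkConfig(n_walkers=1, n_steps=1, kappa_sarco=1e9, D_ics=1.0, D_ecs=2.5)
        start = np.array([28.0, 20.0, 50.0])
        disp = np.array([4.0, 0.0, 0.0])
        p, c, ov = advance_with_membranes(square_cell_substrate, cfg, start, 0, disp)
        expected_x = 30.0 + 2.0 * np.sqrt(2.5 / 1.0)
        assert p[0] == pytest.approx(expected_x, abs=1e-5)
        assert c == ECS


class TestAccumulatePhase:
    def test_stationary_particle_under_refocused_waveform(self, waveforms):
        w = waveforms["PGSE"].with_direction((0, 0, 1.0))
        nt = 5000
        X = np.tile([3.0, -2.0, 7.0], (nt + 1, 1))
        from myowalk.montecarlo import accumulate_phase

        phi = accumulate_phase(X, w, w.T / nt)
        assert abs(phi) < 1e-9 * w.gamma * w.gmax * w.T * 10.0

    def test_constant_velocity_rectangular_pgse_first_moment(self):
        """phi = gamma G v (delta+eps) Delta (e_g . e_v) for trapezoid lobes."""
        from myowalk.montecarlo import accumulate_phase

        spec = SequenceSpec("PGSE", delta=20.0, eps=1.0, Delta=30.0, b=0.6)
        w = make_waveform(spec).with_direction((0, 0, 1.0))
        v = 0.3  # um/ms along z
        nt = 20000
        t = np.linspace(0, w.T, nt + 1)
        X = np.column_stack([np.zeros_like(t), np.zeros_like(t), v * t])
        phi = accumulate_phase(X, w, w.T / nt)
        closed = -w.gamma * w.gmax * v * 21.0 * 30.0
        assert phi == pytest.approx(closed, rel=1e-4)

    def test_constant_velocity_mcse_is_nulled(self, waveforms):
        from myowalk.montecarlo import accumulate_phase

        w = waveforms["MCSE"].with_direction((0, 0, 1.0))
        nt = 20000
        t = np.linspace(0, w.T, nt + 1)
        X = np.column_stack([np.zeros_like(t), np.zeros_like(t), 0.5 * t])
        phi = accumulate_phase(X, w, w.T / nt)
        # quadrature error only: tiny against the PGSE-scale phase
        assert abs(phi) < 1e-4 * w.gamma * w.gmax * 0.5 * w.T**2


class TestSeeding:
    def test_same_seed_identical_ensemble(self, small_substrate):
        cfg = WalkConfig(n_walkers=500, n_steps=1, seed=42)
        a = seed_walkers(small_substrate, cfg)
        b = seed_walkers(small_substrate, cfg)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.comp, b.comp)

    def test_zero_buffer_keeps_walkers_in_voxel(self, small_substrate):
        from dataclasses import replace

        s = replace(small_substrate, buffer=0.0)
        cfg = WalkConfig(n_walkers=2000, n_steps=1, seed=1)
        ens = seed_walkers(s, cfg)
        assert np.all(np.abs(ens.X) <= 0.5 * np.array(s.voxel))

    def test_ecs_fraction_matches_ecv(self, small_packing):
        """Seeding box = whole blocks, so the area ECV is the exact expectation."""
        from myowalk.substrate import TissueBlock, build_substrate

        cs = small_packing
        block = TissueBlock(cs, Lz=127.0)
        s = build_substrate(block, voxel=(2 * cs.Lx, 2 * cs.Ly, 2 * 127.0),
                            ha_rate=0.0, half_shift=False, buffer=0.0)
        cfg = WalkConfig(n_walkers=20_000, n_steps=1, seed=3)
        ens = seed_walkers(s, cfg)
        frac = np.mean(ens.comp == ECS)
        sd = np.sqrt(cs.ecv * (1 - cs.ecv) / cfg.n_walkers)
        assert abs(frac - cs.ecv) < 3 * sd


class TestSignals:
    def test_b_zero_signal_is_unity(self, free_substrate, waveforms):
        cfg = WalkConfig(n_walkers=500, n_steps=100, seed=0)
        df = run_diffusion(free_substrate, cfg, waveforms["PGSE"],
                           directions=[[0, 0, 1.0]], b_values=[0.0, 0.6])
        assert (df.loc[df.b == 0.0, "S_over_S0"] == 1.0).all()
        assert (df["S_over_S0"] <= 1.0).all()

    def test_free_diffusion_recovers_d_ecs(self, free_substrate, waveforms):
        """ln(S)/(-b) equals D_ECS: phase integral and b-value are consistent."""
        cfg = WalkConfig(n_walkers=20_000, n_steps=2000, seed=5)
        for kind in ("PGSE", "MCSE"):
            df = run_diffusion(free_substrate, cfg, waveforms[kind],
                               directions=[[0, 0, 1.0]], b_values=[0.6])
            S = float(df["S_over_S0"].iloc[0])
            adc = -np.log(S) / 0.6
            assert adc == pytest.approx(2.5, rel=0.02)

    def test_signal_monotone_in_b_for_free_diffusion(self, free_substrate, waveforms):
        cfg = WalkConfig(n_walkers=5000, n_steps=500, seed=2)
        df = run_diffusion(free_substrate, cfg, waveforms["PGSE"],
                           directions=[[1.0, 0, 0]], b_values=[0.15, 0.3, 0.6])
        s = df.sort_values("b")["S_over_S0"].to_numpy()
        assert np.all(np.diff(s) < 0)

    def test_determinism_under_seed(self, small_substrate, waveforms):
        cfg = WalkConfig(n_walkers=300, n_steps=100, kappa_sarco=0.02, seed=9)
        a = run_diffusion(small_substrate, cfg, waveforms["PGSE"], b_values=[0.6])
        b = run_diffusion(small_substrate, cfg, waveforms["PGSE"], b_values=[0.6])
        assert np.array_equal(a["S_over_S0"].to_numpy(), b["S_over_S0"].to_numpy())


class TestEquilibrium:
    def test_particle_conservation_and_occupancy_stationary(self, small_substrate,
                                                            waveforms):
        """Detailed balance: ICS fraction is stationary for permeable membranes."""
        cfg = WalkConfig(n_walkers=4000, n_steps=1500, kappa_sarco=0.02, seed=17)
        ens0 = seed_walkers(small_substrate, cfg)
        f0 = float(np.mean(ens0.comp >= 0))
        ens = run_walk(small_substrate, cfg, waveforms["STEAM"],
                       directions=np.array([[0, 0, 1.0]]))
        assert ens.X.shape[0] == cfg.n_walkers  # conservation
        f1 = float(np.mean(ens.comp >= 0))
        sd = np.sqrt(f0 * (1 - f0) / cfg.n_walkers)
        assert abs(f1 - f0) < 3 * sd

    def test_restricted_adc_decreases_with_diffusion_time(self, square_cell_substrate):
        """Impermeable walls, gradient normal to them: ADC falls as Delta grows."""
        adcs = []
        for Delta in (10.0, 40.0, 160.0):
            spec = SequenceSpec("PGSE", delta=2.0, eps=0.5, Delta=Delta, b=0.3)
            w = make_waveform(spec)
            cfg = WalkConfig(n_walkers=3000, n_steps=800, kappa_sarco=0.0, seed=21)
            from dataclasses import replace

            s = replace(square_cell_substrate, buffer=0.0)
            df = run_diffusion(s, cfg, w, directions=[[1.0, 0, 0]], b_values=[0.3])
            adcs.append(-np.log(float(df["S_over_S0"].iloc[0])) / 0.3)
        assert adcs[0] > adcs[1] > adcs[2]

    def test_anisotropy_from_extruded_cells(self, small_substrate, waveforms):
        """lambda1 along the long axis exceeds the transverse eigenvalues."""
        from myowalk.tensorfit import EncodingScheme, fit_from_frame

        scheme = EncodingScheme(b=0.6, bref=0.0)
        cfg = WalkConfig(n_walkers=6000, n_steps=600, kappa_sarco=0.0, seed=13)
        df = run_diffusion(small_substrate, cfg, waveforms["PGSE"],
                           directions=scheme.directions, b_values=[0.0, 0.6])
        r = fit_from_frame(df, scheme)
        assert r.fa > 0.2
        assert r.eigenvalues[0] > r.eigenvalues[1]
        # principal axis close to the mean long axis (global Z)
        assert abs(r.eigenvectors[2, 0]) > 0.95
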
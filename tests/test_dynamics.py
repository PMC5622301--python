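import numpy as np
import pytest

from supercoilsim import (
    FiberSystem,
    ForceFieldParams,
    IntegratorBlowupError,
    IntegratorSettings,
    Simulation,
    autocorrelation_time,
    langevin_step,
    physical_time_per_step,
    run_scenario_replicas,
    wlc_chain,
)

from conftest import perturbed_chain


def straight_system(n=20, box=200.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n, dtype=float)
    side = pos + np.array([0.0, 0.0, 0.5])
    return FiberSystem(positions=pos, side_sites=side, closed=False, box=box)


class TestIntegratorBasics:
    def test_determinism_same_seed(self, params):
        def one():
            sys_ = straight_system(12)
            sim = Simulation(
                sys_, params, IntegratorSettings(dt=2e-3, n_steps=4000, report_every=500, seed=42)
            )
            return sim.run(4000).frames

        a, b = one(), one()
        assert np.array_equal(a, b)

    def test_zero_temperature_relaxed_state_is_stationary(self, params):
        sys_ = straight_system(15)
        st = IntegratorSettings(dt=2e-3, kT=0.0, n_steps=2000, report_every=2000, seed=1)
        sim = Simulation(sys_, params, st)
        traj = sim.run(2000)
        # straight chain with parallel frames is the energy minimum
        assert np.abs(traj.frames[-1] - traj.frames[0]).max() < 1e-9

    def test_blowup_detected_for_overlapping_beads(self, params):
        # a non-bonded pair deep inside the excluded-volume core produces
        # forces no stable step can absorb; the integrator must abort
        sys_ = straight_system(10)
        sys_.positions[6] = sys_.positions[4] + np.array([0.05, 0.02, 0.0])
        sys_.side_sites[6] = sys_.positions[6] + np.array([0.0, 0.0, 0.5])
        st = IntegratorSettings(dt=8e-3, n_steps=200, report_every=200, seed=1)
        with pytest.raises(IntegratorBlowupError):
            Simulation(sys_, params, st).run(200)

    def test_unstable_dt_rejected_upfront(self):
        with pytest.raises(ValueError):
            IntegratorSettings(dt=0.05)

    def test_langevin_step_advances_state(self, params):
        sys_ = straight_system(10)
        sim = Simulation(sys_, params, IntegratorSettings(dt=1e-3, seed=3))
        before = sim.positions.copy()
        langevin_step(sim, 10)
        assert sim.step_count == 10
        assert not np.allclose(sim.positions, before)


class TestEnergyConservation:
    def test_no_thermostat_velocity_verlet_drift(self, params):
        # gamma = 0 reduces BAOAB to velocity Verlet; total energy must be
        # conserved to a tight drift bound at small dt
        pos, side = perturbed_chain(12, seed=6)
        sys_ = FiberSystem(positions=pos, side_sites=side, closed=False, box=100.0)
        st = IntegratorSettings(dt=1e-4, gamma=0.0, n_steps=100, report_every=100, seed=1)
        sim = Simulation(sys_, params, st)
        # seed velocities so kinetic energy is nonzero
        rng = np.random.default_rng(0)
        sim.velocities[:] = 0.3 * rng.standard_normal(sim.velocities.shape)
        energies = []
        n_chunks, chunk = 20, 100
        for _ in range(n_chunks):
            traj = sim.run(chunk)
            pe = traj.energies[-1].sum()
            ke = 0.5 * (sim.velocities**2).sum()
            energies.append(pe + ke)
        drift = np.abs(np.diff(energies)).max() / chunk
        assert drift < 1e-4  # eps0 per step


class TestBoltzmannSampling:
    def test_harmonic_dimer_bond_length_variance(self, params):
        # closed-form Gaussian variance kT / k_bond
        sys_ = straight_system(2)
        st = IntegratorSettings(dt=1e-3, n_steps=800_000, report_every=400, seed=11)
        sim = Simulation(sys_, params, st)
        traj = sim.run(st.n_steps)
        bonds = np.linalg.norm(
            traj.bead_frames()[:, 1] - traj.bead_frames()[:, 0], axis=1
        )
        var = bonds[50:].var()
        assert var == pytest.approx(1.0 / params.k_bond, rel=0.05)

    def test_equipartition_of_bend_and_twist(self, params):
        # 2 transverse bending dofs -> <E_bend> ~ 1 eps0 per interior angle;
        # 1 twist dof -> <E_tor> ~ 0.5 eps0 per bond (k=4 harmonic dihedral)
        rng = np.random.default_rng(5)
        pos, side = wlc_chain(30, rng)
        sys_ = FiberSystem(positions=pos, side_sites=side, closed=False, box=200.0)
        st = IntegratorSettings(dt=1e-3, n_steps=700_000, report_every=1000, seed=8)
        sim = Simulation(sys_, params, st)
        traj = sim.run(st.n_steps)
        f0 = traj.n_frames // 4
        n = sys_.n_beads
        bend = traj.energies[f0:, 2].mean() / (n - 2)
        # KP at eps_bend = 5: <E> = eps_b * (1 - coth(eps_b) + 1/eps_b)
        expected_bend = 5.0 * (1.0 - (1.0 / np.tanh(5.0) - 1.0 / 5.0))
        tor = traj.energies[f0:, 3].mean() / (n - 1)
        assert bend == pytest.approx(expected_bend, rel=0.05)
        assert tor == pytest.approx(0.5, rel=0.05)

    def test_chain_rg_matches_metropolis_oracle(self, params):
        # independent Metropolis (pivot) sampler of the same backbone
        # energetics; frames decouple from the backbone marginal
        n = 40
        rng = np.random.default_rng(2)

        def energy(pos):
            b = np.diff(pos, axis=0)
            bl = np.linalg.norm(b, axis=1)
            e = 0.5 * params.k_bond * ((bl - 1.0) ** 2).sum()
            t = b / bl[:, None]
            e += params.eps_bend * (1.0 - (t[:-1] * t[1:]).sum(axis=1)).sum()
            d = pos[:, None, :] - pos[None, :, :]
            r2 = (d**2).sum(-1)[np.triu_indices(n, k=2)]
            close = r2 < 1.0
            if close.any():
                ir6 = 1.0 / r2[close] ** 3
                e += (4.0 * (ir6**2 - ir6)).sum()
            return e

        def rotmat(axis, ang):
            axis = axis / np.linalg.norm(axis)
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K

        pos, _ = wlc_chain(n, rng)
        e = energy(pos)
        rg2_mc = []
        for m in range(30_000):
            i = rng.integers(1, n - 1)
            new = pos.copy()
            new[i:] = (new[i:] - new[i]) @ rotmat(
                rng.standard_normal(3), rng.normal(0, 0.7)
            ).T + new[i]
            en = energy(new)
            if np.log(rng.random() + 1e-300) < e - en:
                pos, e = new, en
            if m > 5000 and m % 20 == 0:
                c = pos - pos.mean(0)
                rg2_mc.append((c**2).sum(1).mean())
        rg2_mc = np.array(rg2_mc)

        pos0, side0 = wlc_chain(n, np.random.default_rng(77))
        sys_ = FiberSystem(positions=pos0, side_sites=side0, closed=False, box=200.0)
        st = IntegratorSettings(dt=4e-3, n_steps=2_000_000, report_every=2_000, seed=19)
        traj = Simulation(sys_, params, st).run(st.n_steps)
        rg2_md = (traj.rg[traj.n_frames // 5 :] ** 2).mean()
        assert rg2_md == pytest.approx(rg2_mc.mean(), rel=0.03)


class TestAutocorrelationTime:
    def test_white_noise_is_about_one_interval(self):
        x = np.random.default_rng(0).standard_normal(20_000)
        assert autocorrelation_time(x) == pytest.approx(1.0, abs=0.25)

    def test_ar1_matches_closed_form(self):
        # AR(1) with coefficient a has integrated tau = (1 + a) / (1 - a)
        a = 0.9
        rng = np.random.default_rng(3)
        x = np.empty(400_000)
        x[0] = 0.0
        eps = rng.standard_normal(len(x))
        for i in range(1, len(x)):
            x[i] = a * x[i - 1] + eps[i]
        assert autocorrelation_time(x) == pytest.approx((1 + a) / (1 - a), rel=0.15)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(ValueError):
            autocorrelation_time(np.ones(1000))


class TestReplicas:
    def test_distinct_seeds_give_independent_trajectories(self, params):
        st = IntegratorSettings(
            dt=2e-3, n_steps=20_000, report_every=200, seed=5, n_replicas=5,
            thermalization_steps=2_000,
        )

        def factory(rep, seed):
            pos, side = wlc_chain(15, np.random.default_rng(seed))
            return FiberSystem(positions=pos, side_sites=side, closed=False, box=100.0)

        trajs = run_scenario_replicas(factory, st, params)
        assert len(trajs) == 5
        seeds = [t.seed for t in trajs]
        assert len(set(seeds)) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.allclose(trajs[i].frames, trajs[j].frames)
        rgs = np.array([t.rg for t in trajs])
        corr = np.corrcoef(rgs)
        off = corr[np.triu_indices(5, k=1)]
        # individual pair correlations are noisy for slowly-decorrelating Rg
        # series; the average over pairs must be near zero
        assert np.abs(off).mean() < 0.35

    def test_zero_production_returns_thermalized_state_only(self, params):
        st = IntegratorSettings(
            dt=2e-3, n_steps=0, report_every=100, seed=5, n_replicas=1,
            thermalization_steps=500,
        )
        (traj,) = run_scenario_replicas(lambda rep, seed: straight_system(10), st, params)
        assert traj.n_frames == 1 and traj.thermalized

    def test_same_seed_reproduces_bitwise(self, params):
        st = IntegratorSettings(dt=2e-3, n_steps=3000, report_every=300, seed=9,
                                n_replicas=2)
        t1 = run_scenario_replicas(lambda rep, seed: straight_system(12), st, params)
        t2 = run_scenario_replicas(lambda rep, seed: straight_system(12), st, params)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.frames, b.frames)


class TestTimeConversion:
    def test_water_and_nuclear_viscosity_endpoints(self):
        assert physical_time_per_step(1.0) == pytest.approx(5e-6, rel=0.01)
        assert physical_time_per_step(15_000.0) == pytest.approx(0.075, rel=0.01)

    def test_linearity_in_viscosity(self):
        assert physical_time_per_step(2.0) == pytest.approx(
            2.0 * physical_time_per_step(1.0), rel=1e-12
        )

    def test_positive_viscosity_required(self):
        with pytest.raises(ValueError):
            physical_time_per_step(0.0)


class TestPivotSampler:
    def test_ideal_chain_tangent_statistics(self):
        # without excluded volume the pivot ensemble must reproduce the
        # analytic discrete worm-like-chain correlation <cos> = coth(k) - 1/k
        from supercoilsim import ForceFieldParams, pivot_backbone_samples
        from supercoilsim.topology import tangent_correlation

        params = ForceFieldParams(eps_rep=1e-12)
        frames = pivot_backbone_samples(60, n_moves=12_000, seed=4, params=params)
        corr = tangent_correlation(frames, 3)
        expected = 1.0 / np.tanh(5.0) - 0.2
        assert corr[1] == pytest.approx(expected, abs=0.02)

    def test_reproducible_under_seed(self):
        from supercoilsim import pivot_backbone_samples

        a = pivot_backbone_samples(20, n_moves=1_000, seed=9)
        b = pivot_backbone_samples(20, n_moves=1_000, seed=9)
        assert np.array_equal(a, b)
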
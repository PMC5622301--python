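import numpy as np
import pytest

from supercoilsim import (
    FiberSystem,
    ForceFieldParams,
    IntegratorSettings,
    Simulation,
    build_closed_ribbon,
    detect_passage_events,
    linking_number,
    persistence_length,
    plectoneme_passage_configs,
    twist,
    wlc_chain,
    writhe,
)
from supercoilsim.topology import tangent_correlation


def writhe_quadrature(P, closed, sub=40):
    """Independent oracle: midpoint quadrature of the Gauss double integral
    over subdivided polygon segments (non-identical segment pairs)."""
    n = len(P)
    nseg = n if closed else n - 1
    segs = []
    for s in range(nseg):
        a, b = P[s], P[(s + 1) % n]
        ts = (np.arange(sub) + 0.5) / sub
        segs.append((a[None] + ts[:, None] * (b - a)[None], (b - a) / sub))
    total = 0.0
    for i in range(nseg):
        pi, dli = segs[i]
        for j in range(i + 1, nseg):
            pj, dlj = segs[j]
            d = pi[:, None, :] - pj[None, :, :]
            r3 = (d**2).sum(-1) ** 1.5
            total += (d @ np.cross(dli, dlj) / r3).sum()
    return 2 * total / (4 * np.pi)


def torus_knot(p=2, q=5, n=150, scale=2.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 2 + np.cos(q * t)
    return np.c_[r * np.cos(p * t), r * np.sin(p * t), -np.sin(q * t)] * scale


class TestWrithe:
    @pytest.mark.parametrize("n", [8, 20, 64])
    def test_planar_circle_has_zero_writhe(self, n):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        circle = np.c_[np.cos(th), np.sin(th), np.zeros(n)] * 3
        assert abs(writhe(circle, closed=True)) < 1e-10

    def test_mirror_image_negates_writhe_exactly(self, rng):
        curve = torus_knot()
        mirror = curve.copy()
        mirror[:, 2] *= -1
        assert writhe(mirror, closed=True) == -writhe(curve, closed=True)

    def test_matches_fine_quadrature_on_closed_knot(self):
        curve = torus_knot(n=120)
        assert writhe(curve, closed=True) == pytest.approx(
            writhe_quadrature(curve, True), abs=1e-3
        )

    def test_matches_fine_quadrature_on_open_walk(self, rng):
        walk = np.cumsum(rng.standard_normal((50, 3)), axis=0)
        assert writhe(walk, closed=False) == pytest.approx(
            writhe_quadrature(walk, False), abs=1e-3
        )

    def test_coincident_beads_rejected(self):
        pts = np.zeros((6, 3))
        pts[:, 0] = [0, 1, 1, 2, 3, 4]
        with pytest.raises(ValueError):
            writhe(pts)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            writhe(np.eye(3))

    def test_domain_restriction_and_additivity(self):
        # two writhed solenoidal domains joined by a long straight linker:
        # the restricted sums recover the total to within small cross terms
        r, om = 1.5, 0.6
        c = np.sqrt(1.0 - (2 * r * np.sin(om / 2)) ** 2)

        def solenoid(n, x0):
            i = np.arange(n)
            return np.column_stack(
                [x0 + c * i, r * np.cos(om * i), -r * np.sin(om * i)]
            )

        a = solenoid(60, 0.0)
        gap = 40.0
        bridge_t = np.linspace(0, 1, 41)[1:-1]
        b = solenoid(60, a[-1, 0] + gap)
        b[:, 1:] += a[-1, 1:] - b[0, 1:] + 1e-6
        bridge = a[-1] + bridge_t[:, None] * (b[0] - a[-1])
        curve = np.vstack([a, bridge, b])
        w_total = writhe(curve)
        mid = 60 + len(bridge) // 2
        w_a = writhe(curve, bead_range=(0, mid))
        w_b = writhe(curve, bead_range=(mid, len(curve)))
        assert abs(w_a) > 1.0 and abs(w_b) > 1.0  # genuinely writhed domains
        assert abs(w_total - (w_a + w_b)) < 0.05 * (abs(w_a) + abs(w_b))


class TestTwist:
    def test_parallel_transported_frame_has_zero_twist(self, rng):
        pos, side = wlc_chain(60, rng)
        assert twist(side, pos) == pytest.approx(0.0, abs=0.02)
        # the construction projects the transported frame onto vertex
        # tangent planes, leaving a small residual per joint
        assert twist(side, pos, method="pt") == pytest.approx(0.0, abs=0.02)

    def test_uniform_rotation_gives_exactly_one_turn(self):
        # closed circle, frames rotated by 2 pi / n per bond
        sys_ = build_closed_ribbon(40, delta_lk=1.0)
        assert twist(sys_.side_sites, sys_.positions, closed=True) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_dihedral_sum_matches_per_bond_oracle(self, rng):
        from supercoilsim._kernels import dihedral_angle

        pos, side = wlc_chain(25, rng)
        side = side + 0.05 * rng.standard_normal(side.shape)
        total = 0.0
        for b in range(24):
            total += dihedral_angle(
                *side[b], *pos[b], *pos[b + 1], *side[b + 1]
            )
        assert twist(side, pos) == pytest.approx(total / (2 * np.pi), rel=1e-9)


class TestLinkingNumber:
    def test_relaxed_closed_ribbon_is_zero(self):
        sys_ = build_closed_ribbon(60)
        assert linking_number(sys_) == pytest.approx(0.0, abs=1e-9)

    def test_open_chain_rejected(self, rng):
        pos, side = wlc_chain(20, rng)
        sys_ = FiberSystem(positions=pos, side_sites=side, closed=False, box=100.0)
        with pytest.raises(ValueError):
            linking_number(sys_)

    def test_swivel_makes_lk_undefined(self):
        sys_ = build_closed_ribbon(60)
        sys_.swivel_bonds = [5]
        with pytest.raises(ValueError):
            linking_number(sys_)

    def test_identity_and_conservation_under_dynamics(self, params):
        # Lk = Tw + Wr stays at the imposed -3 while twist converts to writhe
        sys_ = build_closed_ribbon(60, delta_lk=-3.0)
        st = IntegratorSettings(dt=4e-3, n_steps=200_000, report_every=10_000, seed=13)
        sim = Simulation(sys_, params, st)
        traj = sim.run(st.n_steps)
        lks = [
            linking_number(sys_, traj.bead_frames()[f], traj.side_frames()[f])
            for f in range(traj.n_frames)
        ]
        assert np.abs(np.array(lks) + 3.0).max() < 1e-2
        # some twist must have converted to writhe along the way
        final_wr = writhe(traj.bead_frames()[-1], closed=True)
        assert final_wr < -0.2


class TestPersistenceLength:
    def test_kratky_porod_scaling_on_ideal_ensembles(self):
        # construction-time WLC samples are exact Boltzmann draws of the
        # bending potential; the fitted Lp follows the discrete KP relation
        rng = np.random.default_rng(8)
        frames10 = np.array([wlc_chain(120, rng, eps_bend=10.0)[0] for _ in range(150)])
        lp10 = persistence_length(frames10)
        expected10 = -10.0 / np.log(1.0 / np.tanh(10.0) - 0.1)
        assert lp10 == pytest.approx(expected10, rel=0.08)
        assert lp10 == pytest.approx(100.0, rel=0.12)

    def test_floppy_limit_approaches_bond_scale(self):
        rng = np.random.default_rng(9)
        frames = np.array([wlc_chain(80, rng, eps_bend=0.5)[0] for _ in range(100)])
        assert persistence_length(frames) < 15.0

    def test_nondecaying_input_rejected(self):
        straight = np.zeros((30, 3))
        straight[:, 0] = np.arange(30)
        with pytest.raises(ValueError):
            persistence_length(straight[None])


class TestPassageDetection:
    def test_constant_series_has_no_events(self):
        assert detect_passage_events(np.zeros(100)) == []

    def test_single_injected_jump_detected_exactly(self):
        w = np.zeros(200)
        w[120:] = -2.0
        events = detect_passage_events(w, steps=np.arange(200) * 10)
        assert len(events) == 1
        assert events[0].step == 1200
        assert events[0].delta_wr == pytest.approx(-2.0)

    def test_threshold_separates_noise_from_jumps(self, rng):
        w = 0.3 * rng.standard_normal(500)
        w[300:] += 2.0
        events = detect_passage_events(w, threshold=1.5)
        assert len(events) == 1 and events[0].delta_wr > 0

    def test_multidomain_series_reports_domain_index(self):
        w = np.zeros((50, 3))
        w[25:, 2] = 2.0
        events = detect_passage_events(w)
        assert [e.domain for e in events] == [2]


class TestPassageSignature:
    def test_single_passage_changes_writhe_by_two(self):
        before, after = plectoneme_passage_configs(separation=1.1)
        dwr = writhe(after, closed=True) - writhe(before, closed=True)
        assert abs(dwr) == pytest.approx(2.0, abs=0.1)

    def test_passage_flips_crossing_sign_symmetrically(self):
        before, after = plectoneme_passage_configs(separation=1.1)
        wb, wa = writhe(before, closed=True), writhe(after, closed=True)
        assert wb * wa < 0  # the crossing changes handedness


class TestTangentCorrelation:
    def test_single_frame_and_batch_agree(self, rng):
        pos, _ = wlc_chain(40, rng)
        c1 = tangent_correlation(pos, 5)
        c2 = tangent_correlation(pos[None], 5)
        assert np.allclose(c1, c2)
        assert c1[0] == pytest.approx(1.0)
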
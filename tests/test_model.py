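import numpy as np
import pytest

from supercoilsim import (
    FiberSystem,
    MotorSpec,
    SystemValidationError,
    beads_to_bp,
    bp_to_beads,
    build_cohesin_system,
    build_closed_ribbon,
    build_from_layout,
    build_linear_system,
    build_loop_system,
    read_layout_bed,
    ring_centreline_diameter_nm,
    validate_system,
    wlc_chain,
)
from supercoilsim.model import _local_tangents


class TestGenomicScale:
    @pytest.mark.parametrize(
        "bp,beads", [(50_000, 125), (0, 0), (800, 2), (400, 1), (600, 2)]
    )
    def test_bp_to_beads(self, bp, beads):
        assert bp_to_beads(bp) == beads

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            bp_to_beads(-1)

    @pytest.mark.parametrize("k", [0, 1, 7, 125, 1500])
    def test_roundtrip_exact_for_multiples_of_400(self, k):
        assert bp_to_beads(beads_to_bp(k)) == k


class TestLoopBuilder:
    def test_fifty_kb_loop_geometry(self):
        sys_ = build_loop_system(50.0, torque_pn_nm=2.0)
        assert sys_.closed
        assert sys_.n_beads == 125
        assert len(sys_.motors) == 2
        # convergent: opposite transcription directions flanking one swivel
        assert sorted(m.direction for m in sys_.motors) == [-1, 1]
        assert len(sys_.swivel_bonds) == 1
        assert not sys_.passage_zones
        # the swivel bond lies between the two motor bonds on the ring
        validate_system(sys_)

    def test_zero_torque_loop_is_valid(self):
        sys_ = build_loop_system(50.0, torque_pn_nm=0.0)
        assert all(m.torque_pn_nm == 0.0 for m in sys_.motors)

    def test_small_loop(self):
        sys_ = build_loop_system(4.0, torque_pn_nm=2.0)
        assert sys_.n_beads == 10
        assert len(sys_.motors) == 2 and len(sys_.swivel_bonds) == 1

    def test_too_small_loop_rejected(self):
        with pytest.raises(ValueError):
            build_loop_system(1.6, torque_pn_nm=2.0)

    def test_starts_as_circle(self):
        sys_ = build_loop_system(20.0, torque_pn_nm=2.0)
        r = np.linalg.norm(sys_.positions - sys_.positions.mean(0), axis=1)
        assert r.std() / r.mean() < 1e-9


class TestLinearBuilder:
    def test_ten_domain_default_scale(self):
        sys_ = build_linear_system([50.0] * 10, torque_pn_nm=2.0, seed=1)
        assert not sys_.closed
        assert len(sys_.motors) == 20  # two per domain
        # 10 x 125 interior + 9 internal borders (14 beads) + 2 terminal (12)
        assert sys_.n_beads == 1250 + 9 * 14 + 2 * 12
        assert len(sys_.layout.borders) == 9
        assert len(sys_.passage_zones) == 11
        assert all(b - a == 10 for a, b in sys_.passage_zones)
        validate_system(sys_)

    def test_border_layout_arithmetic_two_domains(self):
        # 40 kb + 60 kb = 100 + 150 interior beads; recompute indices by hand
        sys_ = build_linear_system([40.0, 60.0], torque_pn_nm=2.0, seed=1)
        assert sys_.layout.interiors == [(12, 112), (126, 276)]
        assert sys_.n_beads == 288
        assert sys_.layout.borders == [119]  # centre of the border zone
        motor_bonds = sorted(m.bond_index for m in sys_.motors)
        assert motor_bonds == [10, 112, 124, 276]
        assert sorted(sys_.swivel_bonds) == [9, 113, 123, 277]

    def test_single_domain_degenerates(self):
        sys_ = build_linear_system([50.0], torque_pn_nm=2.0, seed=0, zones=False)
        assert sys_.n_beads == 133
        assert len(sys_.motors) == 2
        assert sys_.layout.domains == [(2, 131)]

    def test_no_terminal_borders(self):
        sys_ = build_linear_system(
            [50.0], torque_pn_nm=2.0, seed=0, terminal_borders=False
        )
        assert sys_.n_beads == 125 and not sys_.motors

    def test_motor_count_scales_linearly_with_domains(self):
        counts = [
            len(build_linear_system([20.0] * k, seed=0).motors) for k in (1, 2, 4)
        ]
        assert counts == [2, 4, 8]

    def test_sampled_sizes_within_configured_range(self):
        sys_ = build_linear_system(seed=9, n_domains=10)
        lengths = [b - a for a, b in sys_.layout.interiors]
        assert len(lengths) == 10
        assert all(100 <= ell <= 250 for ell in lengths)  # 40-100 kb

    def test_wlc_init_differs_from_straight(self):
        a = build_linear_system([20.0], seed=5, init="wlc")
        b = build_linear_system([20.0], seed=5, init="straight")
        assert not np.allclose(a.positions, b.positions)
        validate_system(a)
        validate_system(b)


class TestCohesinBuilder:
    def test_ring_count_and_spacing(self):
        sys_ = build_cohesin_system(1250, spacing_kb=50.0)
        assert len(sys_.rings) == 10
        anchors = [r.anchor_bead for r in sys_.rings]
        assert anchors == [62 + 125 * i for i in range(10)]
        assert not sys_.motors and not sys_.swivel_bonds and not sys_.passage_zones
        validate_system(sys_)

    def test_spacing_longer_than_chain_gives_one_ring(self):
        sys_ = build_cohesin_system(60, spacing_kb=500.0)
        assert len(sys_.rings) == 1

    def test_ring_centreline_diameter(self):
        d = ring_centreline_diameter_nm()
        assert d == pytest.approx(160.0 / np.pi, abs=0.5)  # ~50.9 nm
        assert d == pytest.approx(50.0, abs=2.0)

    def test_rings_threaded_once(self):
        sys_ = build_cohesin_system(100, spacing_kb=20.0)
        validate_system(sys_)  # includes the threading check
        # displacing a ring off the fibre must fail threading
        sys_.rings[0].ring_positions += np.array([0.0, 30.0, 0.0])
        with pytest.raises(SystemValidationError):
            validate_system(sys_)


class TestValidator:
    def test_motor_on_swivel_rejected(self, small_system):
        small_system.motors = [MotorSpec(3, 1, 2.0)]
        small_system.swivel_bonds = [3]
        with pytest.raises(SystemValidationError):
            validate_system(small_system)

    def test_zone_overlapping_motor_rejected(self, small_system):
        small_system.motors = [MotorSpec(3, 1, 2.0)]
        small_system.passage_zones = [(2, 6)]
        with pytest.raises(SystemValidationError):
            validate_system(small_system)

    def test_overlapping_zones_rejected(self, small_system):
        small_system.passage_zones = [(1, 5), (4, 8)]
        with pytest.raises(SystemValidationError):
            validate_system(small_system)

    def test_side_site_offset_enforced(self, small_system):
        small_system.side_sites[4] += 0.2
        with pytest.raises(SystemValidationError):
            validate_system(small_system)

    def test_motor_spec_invariants(self):
        with pytest.raises(ValueError):
            MotorSpec(0, direction=2, torque_pn_nm=1.0)
        with pytest.raises(ValueError):
            MotorSpec(0, direction=1, torque_pn_nm=-1.0)
        with pytest.raises(ValueError):
            MotorSpec(0, direction=1, torque_pn_nm=1.0, span_beads=3)


class TestWlcChain:
    def test_geometry_invariants(self, rng):
        pos, side = wlc_chain(80, rng)
        bl = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(bl, 1.0, atol=1e-9)
        u = side - pos
        assert np.allclose(np.linalg.norm(u, axis=1), 0.5, atol=1e-9)
        t = _local_tangents(pos, False)
        assert np.abs(np.einsum("ij,ij->i", u, t)).max() < 1e-9

    def test_bend_angle_distribution_matches_boltzmann(self, rng):
        # <cos theta> for p ~ exp(k cos) is coth(k) - 1/k
        cos_t = []
        for _ in range(40):
            pos, _ = wlc_chain(100, rng)
            t = np.diff(pos, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            cos_t.append((t[:-1] * t[1:]).sum(axis=1))
        expected = 1.0 / np.tanh(5.0) - 1.0 / 5.0
        assert np.concatenate(cos_t).mean() == pytest.approx(expected, abs=0.01)


class TestClosedRibbon:
    def test_imposed_delta_lk_lands_in_twist(self):
        from supercoilsim import linking_number, twist, writhe

        sys_ = build_closed_ribbon(100, delta_lk=-6.0)
        assert writhe(sys_.positions, closed=True) == pytest.approx(0.0, abs=1e-9)
        assert twist(sys_.side_sites, sys_.positions, closed=True) == pytest.approx(
            -6.0, abs=0.02
        )
        assert linking_number(sys_) == pytest.approx(-6.0, abs=0.02)


class TestBedLayout:
    def test_roundtrip(self, tmp_path):
        bed = tmp_path / "layout.bed"
        bed.write_text(
            "# layout\n"
            "chrI\t0\t20000\tdomain\n"
            "chrI\t20000\t20800\tmotor+\t2.0\n"
            "chrI\t21200\t21200\tswivel\n"
            "chrI\t21600\t25600\tzone\n"
            "chrI\t25600\t40000\tdomain\n"
        )
        elements = read_layout_bed(bed)
        assert len(elements) == 5
        sys_ = build_from_layout(elements)
        assert sys_.n_beads == 100
        assert sys_.motors[0].bond_index == 50
        assert sys_.motors[0].torque_pn_nm == 2.0
        assert sys_.passage_zones == [(54, 64)]

    def test_unknown_element_type_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chrI\t0\t400\tenhancer\n")
        with pytest.raises(ValueError):
            read_layout_bed(bed)
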
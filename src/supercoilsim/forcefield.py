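"""Force-field terms and parameters of the twistable-fibre model.

All energies are in eps0 = k_B T and lengths in sigma = 10 nm:

* excluded volume: purely repulsive cut-and-shifted Lennard-Jones with
  r_cut = 1 sigma (the shift vanishes identically at that cutoff),
* backbone bonds: harmonic springs at rest length 1 sigma,
* bending: Kratky-Porod ``eps_bend * (1 - cos theta)`` with eps_bend = 5,
  giving a persistence length of ~50 nm,
* torsion: harmonic dihedral ``0.5 * k * phi**2`` on the side-site ladder
  with k = 4 and phi wrapped to (-pi, pi]; zero on swivel bonds,
* motors: a constant external axial torque applied as a pure force couple
  at the motor's gene-body bead (torque in pN nm converted at
  k_B T = 4.1 pN nm); the reaction is absorbed by the implicit solvent,
* passage zones: pair interactions involving a zone bead use a strongly
  reduced excluded-volume prefactor (torsional stiffness is unchanged).

With this bending/torsion stiffness ratio (5 : 4) an imposed linking-number
difference partitions predominantly into writhe at equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels as K
from .model import RING_BEADS, FiberSystem, MotorSpec
from .units import KT_PN_NM

#: sign convention attaching a motor's transcription direction to the axial
#: torque applied on its gene-body-side bead, chosen so that motors drive the
#: twist (and hence writhe) behind them negative, as transcribing RNA
#: polymerases do.
MOTOR_SIGN = -1.0


def zone_epsilon_for_barrier(barrier: float = 2.0, r_pass: float = 0.5) -> float:
    """Excluded-volume prefactor giving pair energy ``barrier`` at ``r_pass``.

    A crossing segment squeezes bead pairs to about half a bead diameter, so
    the prefactor that puts ~2 k_B T there makes thermally driven passages
    possible but not free.  This is the main free parameter controlling the
    intersegmental passage rate.
    """
    sr6 = (1.0 / r_pass) ** 6
    return barrier / (4.0 * (sr6 * sr6 - sr6))


@dataclass
class ForceFieldParams:
    """All potential constants in reduced units plus unit conversions."""

    epsilon0: float = 1.0  # energy unit, k_B T
    sigma: float = 1.0  # length unit, 10 nm
    eps_rep: float = 1.0  # excluded-volume prefactor for normal beads
    r_cut: float = 1.0  # excluded-volume cutoff, sigma
    k_bond: float = 800.0  # backbone bond spring, eps0/sigma^2
    r0_bond: float = 1.0
    eps_bend: float = 5.0  # bending stiffness, eps0
    k_tor: float = 4.0  # torsional stiffness, eps0/rad^2
    zone_epsilon: float = field(default_factory=zone_epsilon_for_barrier)
    kT_pNnm: float = KT_PN_NM  # thermal torque scale, pN nm per eps0
    # side-site ladder bookkeeping (material frame)
    k_side: float = 8000.0  # tether spring, 10 x k_bond
    r0_side: float = 0.5
    k_perp: float = 100.0  # frame-perpendicularity stiffness, eps0
    # cohesin rings
    ring_eps: float = 1.0
    k_anchor: float = 50.0  # ring-centre-to-anchor restraint, eps0/sigma^2

    def __post_init__(self) -> None:
        if self.r_cut > 2 ** (1.0 / 6.0) + 1e-12:
            raise ValueError("r_cut must be <= 2^(1/6) (repulsive-only LJ)")
        if self.zone_epsilon < 0:
            raise ValueError("zone_epsilon must be >= 0")
        for name in ("eps_rep", "k_bond", "eps_bend", "k_tor", "k_side", "k_perp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EnergyBreakdown:
    """Per-term potential energy totals in eps0."""

    excluded_volume: float
    bond: float
    bending: float
    torsion: float
    motor: float
    side_tether: float
    frame_perp: float
    ring_restraint: float

    @property
    def total(self) -> float:
        return (
            self.excluded_volume
            + self.bond
            + self.bending
            + self.torsion
            + self.motor
            + self.side_tether
            + self.frame_perp
            + self.ring_restraint
        )

    @classmethod
    def from_array(cls, e: np.ndarray) -> "EnergyBreakdown":
        return cls(*[float(x) for x in e[:8]])


# ---------------------------------------------------------------------------
# scalar potential functions (reference forms, used directly in tests)
# ---------------------------------------------------------------------------


def excluded_volume_energy(r: float, eps: float = 1.0, r_cut: float = 1.0) -> float:
    """Cut-and-shifted repulsive Lennard-Jones pair energy at distance r."""
    if r <= 0:
        raise ValueError("overlapping beads: r must be > 0")
    if r >= r_cut:
        return 0.0
    sr6 = (1.0 / r) ** 6
    sr6c = (1.0 / r_cut) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) - 4.0 * eps * (sr6c * sr6c - sr6c)


def bending_energy(theta: float, eps_bend: float = 5.0) -> float:
    """Kratky-Porod bending energy for angle theta between bond vectors."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError("theta must be in [0, pi]")
    return eps_bend * (1.0 - math.cos(theta))


def torsion_energy(phi: float, k: float = 4.0) -> float:
    """Harmonic dihedral energy, phi wrapped to (-pi, pi]; 0 for swivels."""
    phi = math.remainder(phi, 2.0 * math.pi)
    return 0.5 * k * phi * phi


def motor_generalized_force(
    spec: MotorSpec, kT_pNnm: float = KT_PN_NM
) -> float:
    """Constant axial torque (eps0/rad) a motor applies to the fibre's twist
    coordinate, signed so that the gene-body (behind) side winds negative.

    The reaction torque is absorbed by the implicit solvent: the motor is an
    external rotary drive, which is what lets torsional stress accumulate
    until the elastic back-torque reaches the motor strength (stalling).
    """
    return MOTOR_SIGN * spec.direction * spec.torque_pn_nm / kT_pNnm


def motor_behind_bead(spec: MotorSpec) -> int:
    """Bead of the motor bond on the gene-body side (behind the polymerase)."""
    return spec.bond_index if spec.direction > 0 else spec.bond_index + 1


# ---------------------------------------------------------------------------
# system packing and full force evaluation
# ---------------------------------------------------------------------------


class PackedSystem:
    """Flat array view of a FiberSystem + ForceFieldParams for the kernels."""

    def __init__(self, system: FiberSystem, params: ForceFieldParams):
        n = system.n_beads
        nb = system.n_bonds
        self.n = n
        self.closed = system.closed
        self.box = float(system.box)
        self.params = params
        self.eps_pair = np.full(n, params.eps_rep)
        self.eps_pair[system.zone_beads()] = params.zone_epsilon
        self.k_tor = np.full(nb, params.k_tor)
        for b in system.swivel_bonds:
            self.k_tor[b] = 0.0
        n_mot = len(system.motors)
        self.mot_bead = np.empty(n_mot, dtype=np.int64)
        self.mot_ax_i = np.empty(n_mot, dtype=np.int64)
        self.mot_ax_j = np.empty(n_mot, dtype=np.int64)
        self.mot_c = np.empty(n_mot)
        for k, m in enumerate(system.motors):
            if self.k_tor[m.bond_index] == 0.0:
                raise ValueError(
                    f"motor on swivel bond {m.bond_index}: contradictory annotation"
                )
            self.mot_bead[k] = motor_behind_bead(m) % n
            self.mot_ax_i[k] = m.bond_index
            self.mot_ax_j[k] = (m.bond_index + 1) % n
            self.mot_c[k] = motor_generalized_force(m, params.kT_pNnm)
        self.ring_anchor = np.array(
            [r.anchor_bead for r in system.rings], dtype=np.int64
        )
        self.n_rings = len(system.rings)
        if self.n_rings:
            rel = system.rings[0].ring_positions - system.rings[0].ring_positions.mean(
                axis=0
            )
            # body template shared by all rings; orientations stored per ring
            self.ring_body = _ring_template(rel.shape[0])
            self.ring_orient = np.empty((self.n_rings, 3, 3))
            for i, ring in enumerate(system.rings):
                self.ring_orient[i] = _orientation_from_positions(
                    ring.ring_positions, self.ring_body
                )
        else:
            self.ring_body = np.zeros((RING_BEADS, 3))
            self.ring_orient = np.zeros((0, 3, 3))
        gamma = 1.0
        self.gamma_ring_t = gamma * RING_BEADS
        self.gamma_ring_r = gamma * float((self.ring_body ** 2).sum())

    @property
    def n_sites(self) -> int:
        return 2 * self.n + self.n_rings * RING_BEADS


def _ring_template(n_ring_beads: int = RING_BEADS) -> np.ndarray:
    radius = 0.5 / np.sin(np.pi / n_ring_beads)
    ang = 2.0 * np.pi * np.arange(n_ring_beads) / n_ring_beads
    return np.column_stack(
        [np.zeros(n_ring_beads), radius * np.cos(ang), radius * np.sin(ang)]
    )


def _orientation_from_positions(ring_pos: np.ndarray, body: np.ndarray) -> np.ndarray:
    """Least-squares rotation (Kabsch) mapping body coords onto lab coords."""
    rel = ring_pos - ring_pos.mean(axis=0)
    h = body.T @ rel
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return (vt.T @ corr @ u.T)


def compute_forces(
    system: FiberSystem,
    params: ForceFieldParams | None = None,
    positions: np.ndarray | None = None,
) -> tuple[np.ndarray, EnergyBreakdown]:
    """Forces on all sites (beads, side sites, ring beads) and energy terms.

    Forces are the exact negative gradient of the total energy; the motor
    term contributes its constant generalized torque through the dihedral
    gradient.
    """
    params = params or ForceFieldParams()
    packed = PackedSystem(system, params)
    pos = np.asarray(positions if positions is not None else system.sites(), float)
    if pos.shape != (packed.n_sites, 3):
        raise ValueError(f"expected positions of shape {(packed.n_sites, 3)}")
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite coordinates")
    n_ring_sites = packed.n_rings * RING_BEADS
    max_pairs = (packed.n + n_ring_sites) ** 2 // 2 + 16
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    npairs = K.build_pairs(
        pos, packed.n, packed.closed, n_ring_sites, packed.box, params.r_cut, pairs
    )
    forces = np.zeros_like(pos)
    energies = np.zeros(8)
    f_rc = np.zeros((packed.n_rings, 3))
    K.compute_forces(
        pos,
        packed.n,
        packed.closed,
        packed.box,
        packed.eps_pair,
        params.r_cut,
        params.k_bond,
        params.r0_bond,
        params.eps_bend,
        packed.k_tor,
        packed.mot_bead,
        packed.mot_ax_i,
        packed.mot_ax_j,
        packed.mot_c,
        params.k_side,
        params.r0_side,
        params.k_perp,
        params.ring_eps,
        packed.ring_anchor,
        params.k_anchor,
        pairs,
        npairs,
        forces,
        energies,
        f_rc,
    )
    return forces, EnergyBreakdown.from_array(energies)
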
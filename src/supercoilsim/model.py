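"""Construction of twistable-fibre simulation systems.

A system is a beaded chain (one bead = 400 bp = 10 nm) carrying a material
frame realised as phantom side sites offset 0.5 sigma perpendicular to the
local tangent.  Annotations mark the active elements of the transcription /
topoisomerase model:

* **motors** — RNA-polymerase-like torsional motors: a constant torque applied
  to the side-site dihedral of one bond (the motor occupies the bond's two
  beads, i.e. 800 bp),
* **swivels** — bonds with zero torsional stiffness (TOP1-like free rotation),
* **passage zones** — bead stretches with strongly softened excluded volume
  through which other fibre segments can pass thermally (TOP2-like),
* **cohesin rings** — rigid circles of 16 tangent 10 nm beads threaded on the
  fibre and restrained to an anchor bead.

Borders between divergent-transcription domains follow the layout of the
model: two convergent motors, a swivel "ahead" of each motor (on the side the
motor points toward, offset one bond by default) and one 10-bead passage zone
between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import BP_PER_BEAD, SIGMA_NM, bp_to_beads

#: beads per cohesin ring
RING_BEADS = 16

#: default passage-zone length in beads
ZONE_BEADS = 10

#: swivel offset "ahead of" a motor, in bonds
SWIVEL_OFFSET = 1


def ring_centreline_diameter_nm(
    n_ring_beads: int = RING_BEADS, bead_diameter_nm: float = SIGMA_NM
) -> float:
    """Diameter of the circle through the centres of n mutually tangent beads.

    Sixteen tangent 10 nm beads give ~51.3 nm, the ~50 nm cohesin ring of the
    barrier model.
    """
    return bead_diameter_nm / np.sin(np.pi / n_ring_beads)


@dataclass
class MotorSpec:
    """A static torsional motor acting on one bond's dihedral coordinate.

    ``direction`` is the sense of transcription along the chain (+1 toward
    increasing bead index); the applied torque drives negative twist on the
    upstream (gene-body) side, as a transcribing polymerase does.
    """

    bond_index: int
    direction: int
    torque_pn_nm: float
    span_beads: int = 2

    def __post_init__(self) -> None:
        if abs(self.direction) != 1:
            raise ValueError(f"motor direction must be +-1, got {self.direction}")
        if self.torque_pn_nm < 0:
            raise ValueError("motor torque must be >= 0")
        if self.span_beads != 2:
            raise ValueError("motors span exactly 2 beads (800 bp)")


@dataclass
class CohesinRing:
    """A rigid ring of 16 tangent 10 nm beads encircling the fibre."""

    anchor_bead: int
    ring_positions: np.ndarray  # (16, 3), sigma units
    n_ring_beads: int = RING_BEADS
    bead_diameter_nm: float = SIGMA_NM


@dataclass
class DomainLayout:
    """Bead ranges of divergent-transcription domains and their borders.

    ``domains`` are half-open bead ranges; by default they include the two
    flanking motor beads (toggle via ``include_motor_beads`` when measuring).
    ``interiors`` are the same ranges without motor beads.  ``borders`` are
    the motor-convergence bead positions used for boundary-coincidence
    scoring.
    """

    domains: list[tuple[int, int]]
    interiors: list[tuple[int, int]]
    borders: list[int]

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def writhe_ranges(self, include_motor_beads: bool = True) -> list[tuple[int, int]]:
        return list(self.domains if include_motor_beads else self.interiors)


@dataclass
class FiberSystem:
    """Geometry plus annotations of one simulated chromatin fibre."""

    positions: np.ndarray  # (n, 3) backbone beads, sigma units
    side_sites: np.ndarray  # (n, 3) material-frame sites
    closed: bool
    box: float  # periodic box edge, sigma units
    motors: list[MotorSpec] = field(default_factory=list)
    swivel_bonds: list[int] = field(default_factory=list)
    passage_zones: list[tuple[int, int]] = field(default_factory=list)
    rings: list[CohesinRing] = field(default_factory=list)
    layout: DomainLayout | None = None

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.n_beads if self.closed else self.n_beads - 1

    @property
    def bonds(self) -> np.ndarray:
        """Ordered (i, j) bead pairs forming the single chain path."""
        n = self.n_beads
        i = np.arange(self.n_bonds)
        return np.column_stack([i, (i + 1) % n])

    def sites(self) -> np.ndarray:
        """Stacked coordinates: beads, side sites, then ring beads."""
        parts = [self.positions, self.side_sites]
        for ring in self.rings:
            parts.append(ring.ring_positions)
        return np.vstack(parts)

    def zone_beads(self) -> np.ndarray:
        """Boolean mask of beads inside passage zones."""
        mask = np.zeros(self.n_beads, dtype=bool)
        for a, b in self.passage_zones:
            mask[a:b] = True
        return mask

    def copy(self) -> "FiberSystem":
        return replace(
            self,
            positions=self.positions.copy(),
            side_sites=self.side_sites.copy(),
            motors=list(self.motors),
            swivel_bonds=list(self.swivel_bonds),
            passage_zones=list(self.passage_zones),
            rings=[
                replace(r, ring_positions=r.ring_positions.copy()) for r in self.rings
            ],
        )

    def validate(self) -> None:
        validate_system(self)


class SystemValidationError(ValueError):
    """Raised when a constructed system violates a structural invariant."""


def validate_system(system: FiberSystem) -> None:
    """Check connectivity, frame geometry, annotation disjointness, threading."""
    n = system.n_beads
    if n < 2:
        raise SystemValidationError("need at least 2 beads")
    if not np.all(np.isfinite(system.positions)):
        raise SystemValidationError("non-finite bead coordinates")

    # side-site offset distance and orthogonality to the local tangent
    u = system.side_sites - system.positions
    d = np.linalg.norm(u, axis=1)
    if np.any(np.abs(d - 0.5) > 1e-6):
        raise SystemValidationError("side-site offset must be 0.5 sigma")
    tangents = _local_tangents(system.positions, system.closed)
    dots = np.abs(np.einsum("ij,ij->i", u / d[:, None], tangents))
    if np.any(dots > 1e-6):
        raise SystemValidationError("side sites must be perpendicular to tangent")

    nb = system.n_bonds
    motor_bonds = [m.bond_index for m in system.motors]
    for b in motor_bonds + list(system.swivel_bonds):
        if not 0 <= b < nb:
            raise SystemValidationError(f"bond index {b} out of range")
    if len(set(motor_bonds)) != len(motor_bonds):
        raise SystemValidationError("duplicate motor bonds")
    if set(motor_bonds) & set(system.swivel_bonds):
        raise SystemValidationError("motor on a swivel bond")

    zone_mask = np.zeros(n, dtype=int)
    for a, b in system.passage_zones:
        if not (0 <= a < b <= n):
            raise SystemValidationError(f"bad zone range ({a}, {b})")
        zone_mask[a:b] += 1
    if np.any(zone_mask > 1):
        raise SystemValidationError("overlapping passage zones")
    motor_beads = set()
    for m in system.motors:
        motor_beads.add(m.bond_index)
        motor_beads.add((m.bond_index + 1) % n)
    if any(zone_mask[i] for i in motor_beads):
        raise SystemValidationError("passage zone overlaps motor beads")

    for ring in system.rings:
        if not 0 <= ring.anchor_bead < n:
            raise SystemValidationError("ring anchor out of range")
        crossings = _disc_crossings(system.positions, system.closed, ring)
        if crossings != 1:
            raise SystemValidationError(
                f"ring at bead {ring.anchor_bead} crossed {crossings} times "
                "(must be threaded exactly once)"
            )


def _local_tangents(positions: np.ndarray, closed: bool) -> np.ndarray:
    """Unit tangent per bead (central difference, one-sided at open ends)."""
    if closed:
        t = np.roll(positions, -1, axis=0) - np.roll(positions, 1, axis=0)
    else:
        t = np.empty_like(positions)
        t[1:-1] = positions[2:] - positions[:-2]
        t[0] = positions[1] - positions[0]
        t[-1] = positions[-1] - positions[-2]
    return t / np.linalg.norm(t, axis=1)[:, None]


def _disc_crossings(positions: np.ndarray, closed: bool, ring: CohesinRing) -> int:
    """Number of chain segments crossing the ring's open disc."""
    centre = ring.ring_positions.mean(axis=0)
    rel = ring.ring_positions - centre
    normal = np.cross(rel[0], rel[RING_BEADS // 4])
    normal /= np.linalg.norm(normal)
    radius = np.linalg.norm(rel, axis=1).mean() - 0.5  # opening radius
    n = positions.shape[0]
    n_seg = n if closed else n - 1
    count = 0
    for s in range(n_seg):
        a = positions[s]
        b = positions[(s + 1) % n]
        ha = (a - centre) @ normal
        hb = (b - centre) @ normal
        # consistent tie-break for beads exactly in the ring plane
        ha = ha if ha != 0 else 1e-12
        hb = hb if hb != 0 else 1e-12
        if ha == hb or (ha > 0) == (hb > 0):
            continue
        t = ha / (ha - hb)
        p = a + t * (b - a)
        if np.linalg.norm(p - centre - ((p - centre) @ normal) * normal) < radius:
            count += 1
    return count


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _expected_rg(n_beads: int, lp_beads: float = 5.0) -> float:
    """Worm-like-chain estimate of Rg in sigma (ideal, L >> Lp)."""
    return float(np.sqrt(max(lp_beads * n_beads / 3.0, 1.0)))


def _straight_chain(n: int) -> tuple[np.ndarray, np.ndarray]:
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n, dtype=float)
    side = pos + np.array([0.0, 0.0, 0.5])
    return pos, side


def wlc_chain(
    n: int,
    rng: np.random.Generator,
    eps_bend: float = 5.0,
    min_dist: float = 0.9,
    max_tries: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample an equilibrium Kratky-Porod chain with soft self-avoidance.

    Bond angles are drawn from the Boltzmann distribution of the bending
    potential (``p(cos t) ~ exp(eps_bend cos t)``), azimuths uniformly; beads
    closer than ``min_dist`` to any predecessor are resampled.  The material
    frame is parallel-transported (twist-free).  Used as a pre-equilibrated
    start that skips the slow global collapse of a straight chain.
    """
    pos = np.zeros((n, 3))
    t = np.zeros((n - 1, 3))
    t[0] = (1.0, 0.0, 0.0)
    pos[1] = pos[0] + t[0]
    for i in range(1, n - 1):
        prev = t[i - 1]
        # orthonormal basis around prev
        a = np.array([0.0, 0.0, 1.0]) if abs(prev[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev, e1)
        for _ in range(max_tries):
            u = rng.random()
            cos_t = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * eps_bend)) / eps_bend
            sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            phi = 2.0 * np.pi * rng.random()
            cand = cos_t * prev + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
            new = pos[i] + cand
            d2 = ((pos[: max(0, i - 1)] - new) ** 2).sum(axis=1)
            if d2.size == 0 or d2.min() >= min_dist * min_dist:
                break
        t[i] = cand
        pos[i + 1] = new
    # twist-free frame: parallel transport, projected onto the central tangent
    u = np.cross(t[0], np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(t[0], np.array([0.0, 1.0, 0.0]))
    u /= np.linalg.norm(u)
    side = np.empty_like(pos)
    tangents = _local_tangents(pos, False)
    for i in range(n):
        if i > 0:
            u = _transport(u, t[i - 1] if i - 1 < n - 1 else t[-1], t[min(i, n - 2)])
        ui = u - (u @ tangents[i]) * tangents[i]
        ui /= np.linalg.norm(ui)
        side[i] = pos[i] + 0.5 * ui
    return pos, side


def _transport(u: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Parallel transport u across the rotation taking t_from to t_to."""
    axis = np.cross(t_from, t_to)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return u
    axis = axis / s
    c = float(np.clip(t_from @ t_to, -1.0, 1.0))
    return u * c + np.cross(axis, u) * s + axis * (axis @ u) * (1.0 - c)


def _circle_chain(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed ring of unit-length bonds with torsionally relaxed frame."""
    radius = 0.5 / np.sin(np.pi / n)
    ang = 2.0 * np.pi * np.arange(n) / n
    pos = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    side = pos + np.array([0.0, 0.0, 0.5])
    return pos, side


def build_loop_system(domain_kb: float, torque_pn_nm: float) -> FiberSystem:
    """Closed divergently-transcribed domain: the small chromatin loop model.

    The loop's closure point is flanked by two convergent motors with one
    swivel bond between them; the fibre starts as a near-perfect circle.
    Motor beads are carved from the domain's bead budget, so a 50 kb loop has
    125 beads and a 4 kb loop 10.
    """
    if domain_kb <= 1:
        raise ValueError("loop domain must be larger than 1 kb")
    n = bp_to_beads(domain_kb * 1000.0)
    if n < 7:
        raise ValueError(
            f"domain of {domain_kb} kb ({n} beads) too small to host two "
            "2-bead motors and a swivel"
        )
    pos, side = _circle_chain(n)
    motors = [
        MotorSpec(bond_index=0, direction=-1, torque_pn_nm=torque_pn_nm),
        MotorSpec(bond_index=n - 2, direction=+1, torque_pn_nm=torque_pn_nm),
    ]
    swivels = [n - 1]  # closure bond, between the two motors
    diameter = 1.0 / np.sin(np.pi / n)
    box = max(4.0 * _expected_rg(n), 2.0 * diameter)
    layout = DomainLayout(domains=[(0, n)], interiors=[(2, n - 2)], borders=[0])
    system = FiberSystem(
        positions=pos,
        side_sites=side,
        closed=True,
        box=box,
        motors=motors,
        swivel_bonds=swivels,
        layout=layout,
    )
    validate_system(system)
    return system


def build_closed_ribbon(n_beads: int, delta_lk: float = 0.0) -> FiberSystem:
    """Passive closed fibre, optionally with an imposed linking-number change.

    ``delta_lk`` is wound uniformly into the side-site frame, so the ribbon
    starts as a flat circle with Tw = delta_lk and Wr = 0; dynamics then
    repartitions it between twist and writhe at fixed Lk.
    """
    if n_beads < 8:
        raise ValueError("closed ribbon needs at least 8 beads")
    pos, side = _circle_chain(n_beads)
    if delta_lk:
        tangents = _local_tangents(pos, True)
        u = side - pos
        theta = 2.0 * np.pi * delta_lk * np.arange(n_beads) / n_beads
        for i in range(n_beads):
            u[i] = _rotate_about(u[i], tangents[i], theta[i])
        side = pos + u
    box = max(4.0 * _expected_rg(n_beads), 2.5 / np.sin(np.pi / n_beads))
    system = FiberSystem(positions=pos, side_sites=side, closed=True, box=box)
    validate_system(system)
    return system


def _rotate_about(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(theta), np.sin(theta)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def sample_domain_sizes_kb(
    n_domains: int,
    rng: np.random.Generator,
    low_kb: float = 40.0,
    high_kb: float = 100.0,
) -> list[float]:
    """Draw domain sizes approximating the S. pombe 50-100 kb domain-size
    distribution (uniform on [40, 100] kb by default; configurable)."""
    return list(rng.uniform(low_kb, high_kb, size=n_domains))


def build_linear_system(
    domain_sizes_kb: list[float] | None = None,
    torque_pn_nm: float = 2.0,
    seed: int | None = None,
    n_domains: int = 10,
    terminal_borders: bool = True,
    zones: bool = True,
    box: float | None = None,
    init: str = "wlc",
) -> FiberSystem:
    """Linear chromosome fragment with divergent-transcription domains.

    Every internal border carries two convergent motors, a swivel ahead of
    each motor and (by default) one 10-bead passage zone between the swivels.
    With ``terminal_borders`` the chain ends get the outward-facing half of a
    border as well; without ``zones`` borders use a 2-bead spacer instead of
    the passage zone (and chain ends a 2-bead tail).  The starting
    configuration is an equilibrium worm-like-chain sample (``init="wlc"``,
    twist-free frame) or a straight rod (``init="straight"``).
    """
    rng = np.random.default_rng(0 if seed is None else seed)
    if domain_sizes_kb is None:
        domain_sizes_kb = sample_domain_sizes_kb(n_domains, rng)
    if len(domain_sizes_kb) < 1:
        raise ValueError("need at least one domain")
    dom_beads = [bp_to_beads(kb * 1000.0) for kb in domain_sizes_kb]
    if min(dom_beads) < 5:
        raise ValueError("domains must be at least 2 kb (5 beads)")

    gap = ZONE_BEADS if zones else 2  # beads between the two border swivels
    motors: list[MotorSpec] = []
    swivels: list[int] = []
    zone_list: list[tuple[int, int]] = []
    domains: list[tuple[int, int]] = []
    interiors: list[tuple[int, int]] = []
    borders: list[int] = []

    cursor = 0
    if terminal_borders:
        # left terminal border: [gap/zone][swivel][motor pointing left]
        if zones:
            zone_list.append((cursor, cursor + gap))
        cursor += gap
        swivels.append(cursor - 1)  # bond (gap-1, gap)
        motors.append(MotorSpec(cursor, -1, torque_pn_nm))
        cursor += 2

    for d, nd in enumerate(dom_beads):
        has_left_border = terminal_borders or d > 0
        interiors.append((cursor, cursor + nd))
        cursor += nd
        has_right_border = d < len(dom_beads) - 1 or terminal_borders
        if has_right_border:
            motors.append(MotorSpec(cursor, +1, torque_pn_nm))
            cursor += 2
            swivels.append(cursor - 1)  # bond just ahead of the motor
            if d < len(dom_beads) - 1:
                borders.append(cursor + gap // 2)
            if zones:
                zone_list.append((cursor, cursor + gap))
            cursor += gap
            if d < len(dom_beads) - 1:
                swivels.append(cursor - 1)
                motors.append(MotorSpec(cursor, -1, torque_pn_nm))
                cursor += 2
        # domain range including the flanking motor beads
        domains.append(
            (
                interiors[-1][0] - (2 if has_left_border else 0),
                interiors[-1][1] + (2 if has_right_border else 0),
            )
        )

    n = cursor
    if init == "wlc":
        pos, side = wlc_chain(n, rng)
    elif init == "straight":
        pos, side = _straight_chain(n)
    else:
        raise ValueError(f"unknown init {init!r}")
    if box is None:
        extent = float(np.ptp(pos, axis=0).max())
        box = max(4.0 * _expected_rg(n), 1.5 * extent)
    layout = DomainLayout(domains=domains, interiors=interiors, borders=borders)
    system = FiberSystem(
        positions=pos,
        side_sites=side,
        closed=False,
        box=box,
        motors=motors,
        swivel_bonds=swivels,
        passage_zones=zone_list,
        layout=layout,
    )
    validate_system(system)
    return system


def _ring_body_coords() -> np.ndarray:
    """Body-frame coordinates of the 16 ring beads (circle in the yz plane)."""
    radius = 0.5 / np.sin(np.pi / RING_BEADS)
    ang = 2.0 * np.pi * np.arange(RING_BEADS) / RING_BEADS
    return np.column_stack(
        [np.zeros(RING_BEADS), radius * np.cos(ang), radius * np.sin(ang)]
    )


def build_cohesin_system(
    n_beads: int,
    spacing_kb: float = 50.0,
    box: float | None = None,
) -> FiberSystem:
    """Cohesin-barrier model: passive fibre with threaded rigid rings.

    No motors, swivels or passage zones; rigid 16-bead rings are threaded on
    the straight starting fibre at ~``spacing_kb`` genomic spacing, each
    restrained to its anchor bead.
    """
    if n_beads < 4:
        raise ValueError("chain too short")
    spacing_beads = max(1, bp_to_beads(spacing_kb * 1000.0))
    pos, side = _straight_chain(n_beads)
    body = _ring_body_coords()
    n_rings = max(1, n_beads // spacing_beads)
    anchors = [
        min(max(spacing_beads // 2 + i * spacing_beads, 1), n_beads - 2)
        for i in range(n_rings)
    ]
    rings = [
        CohesinRing(anchor_bead=a, ring_positions=body + pos[a]) for a in anchors
    ]
    if box is None:
        box = max(4.0 * _expected_rg(n_beads), 1.25 * n_beads)
    layout = DomainLayout(
        domains=[], interiors=[], borders=[]
    )
    system = FiberSystem(
        positions=pos,
        side_sites=side,
        closed=False,
        box=box,
        rings=rings,
        layout=layout,
    )
    validate_system(system)
    return system


# ---------------------------------------------------------------------------
# BED-like layout input
# ---------------------------------------------------------------------------

_ELEMENT_TYPES = {"domain", "motor+", "motor-", "swivel", "zone", "ring"}


def read_layout_bed(path) -> list[dict]:
    """Parse a BED-like annotation: chrom, start, end, element_type[, torque].

    Coordinates are 0-based half-open base pairs, converted at 400 bp/bead.
    Element types: domain, motor+ / motor- (direction of transcription),
    swivel, zone, ring.
    """
    elements = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: need >= 4 columns")
            chrom, start, end, etype = parts[:4]
            if etype not in _ELEMENT_TYPES:
                raise ValueError(f"{path}:{ln}: unknown element type {etype!r}")
            torque = float(parts[4]) if len(parts) > 4 else 0.0
            elements.append(
                {
                    "chrom": chrom,
                    "start_bead": bp_to_beads(int(start)),
                    "end_bead": bp_to_beads(int(end)),
                    "type": etype,
                    "torque_pn_nm": torque,
                }
            )
    return elements


def build_from_layout(elements: list[dict], box: float | None = None) -> FiberSystem:
    """Assemble a linear system from parsed BED-like elements."""
    if not elements:
        raise ValueError("empty layout")
    n = max(e["end_bead"] for e in elements)
    pos, side = _straight_chain(n)
    motors: list[MotorSpec] = []
    swivels: list[int] = []
    zone_list: list[tuple[int, int]] = []
    rings: list[CohesinRing] = []
    domains: list[tuple[int, int]] = []
    body = _ring_body_coords()
    for e in elements:
        a, b = e["start_bead"], e["end_bead"]
        if e["type"] == "domain":
            domains.append((a, b))
        elif e["type"] in ("motor+", "motor-"):
            direction = 1 if e["type"] == "motor+" else -1
            motors.append(MotorSpec(a, direction, e["torque_pn_nm"]))
        elif e["type"] == "swivel":
            swivels.append(a)
        elif e["type"] == "zone":
            zone_list.append((a, b))
        elif e["type"] == "ring":
            anchor = (a + b) // 2
            rings.append(CohesinRing(anchor, body + pos[anchor]))
    if box is None:
        box = max(4.0 * _expected_rg(n), 1.25 * n)
    layout = DomainLayout(
        domains=domains,
        interiors=domains,
        borders=[(domains[i][1] + domains[i + 1][0]) // 2 for i in range(len(domains) - 1)],
    )
    system = FiberSystem(
        positions=pos,
        side_sites=side,
        closed=False,
        box=box,
        motors=motors,
        swivel_bonds=swivels,
        passage_zones=zone_list,
        rings=rings,
        layout=layout,
    )
    validate_system(system)
    return system
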
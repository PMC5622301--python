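"""Numba kernels: force evaluation, Langevin propagation, topology sums.

Site layout convention used by every kernel:

* ``pos[0:n]``        backbone beads (the fibre axis),
* ``pos[n:2n]``       side sites (material-frame markers, one per bead),
* ``pos[2n:]``        cohesin-ring beads, 16 consecutive sites per ring.

All quantities are in reduced units: length sigma (10 nm), energy eps0
(k_B T), friction gamma and bead mass 1.  Positions are kept unwrapped;
periodic boundaries enter only through minimum-image displacements in the
non-bonded loop.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

RING_BEADS = 16

# status codes returned by the run kernel
STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_PAIR_OVERFLOW = 2


# ---------------------------------------------------------------------------
# small geometry helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _min_image(d: float, box: float) -> float:
    if box > 0.0:
        return d - box * math.floor(d / box + 0.5)
    return d


@njit(cache=True)
def dihedral_angle(
    p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z, p4x, p4y, p4z
) -> float:
    """Signed dihedral (IUPAC convention) of the four points, in (-pi, pi]."""
    b1x = p2x - p1x
    b1y = p2y - p1y
    b1z = p2z - p1z
    b2x = p3x - p2x
    b2y = p3y - p2y
    b2z = p3z - p2z
    b3x = p4x - p3x
    b3y = p4y - p3y
    b3z = p4z - p3z
    # n1 = b1 x b2 ; n2 = b2 x b3
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    # m = n1 x n2
    mx = n1y * n2z - n1z * n2y
    my = n1z * n2x - n1x * n2z
    mz = n1x * n2y - n1y * n2x
    y = (mx * b2x + my * b2y + mz * b2z) / nb2 if nb2 > 0.0 else 0.0
    x = n1x * n2x + n1y * n2y + n1z * n2z
    return math.atan2(y, x)


# ---------------------------------------------------------------------------
# neighbour list
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def build_pairs(pos, n, closed, n_ring_sites, box, cutoff, pairs):
    """All-pairs neighbour search over backbone + ring sites.

    Adjacent backbone beads (and the closure pair of a ring polymer) are
    excluded, as are same-ring bead pairs (rigid).  Returns the pair count or
    -1 on overflow of the preallocated ``pairs`` array.
    """
    max_pairs = pairs.shape[0]
    cutoff2 = cutoff * cutoff
    n_nb = n + n_ring_sites
    count = 0
    for a in range(n_nb):
        ia = a if a < n else 2 * n + (a - n)
        for b in range(a + 1, n_nb):
            if a < n and b < n:
                if b - a == 1:
                    continue
                if closed and a == 0 and b == n - 1:
                    continue
            elif a >= n and b >= n:
                if (a - n) // RING_BEADS == (b - n) // RING_BEADS:
                    continue
            ib = b if b < n else 2 * n + (b - n)
            dx = _min_image(pos[ia, 0] - pos[ib, 0], box)
            dy = _min_image(pos[ia, 1] - pos[ib, 1], box)
            dz = _min_image(pos[ia, 2] - pos[ib, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cutoff2:
                if count >= max_pairs:
                    return -1
                pairs[count, 0] = ia
                pairs[count, 1] = ib
                count += 1
    return count


# ---------------------------------------------------------------------------
# forces and energies
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,
    n,
    closed,
    box,
    eps_pair,
    r_cut,
    k_bond,
    r0_bond,
    eps_bend,
    k_tor,
    mot_bead,
    mot_ax_i,
    mot_ax_j,
    mot_c,
    k_side,
    r0_side,
    k_perp,
    ring_eps,
    ring_anchor,
    k_anchor,
    pairs,
    n_pairs,
    forces,
    energies,
    f_ring_centers,
):
    """Fill ``forces`` with -grad E and ``energies`` with the term breakdown.

    Energy channels: 0 excluded volume, 1 backbone bonds, 2 bending,
    3 torsion, 4 motor work term (always 0: the motor couple is
    nonconservative), 5 side-site tethers, 6 frame-perpendicularity,
    7 ring anchor restraints.
    """
    n_sites = pos.shape[0]
    for i in range(n_sites):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    for i in range(8):
        energies[i] = 0.0
    n_rings = ring_anchor.shape[0]
    for r in range(n_rings):
        f_ring_centers[r, 0] = 0.0
        f_ring_centers[r, 1] = 0.0
        f_ring_centers[r, 2] = 0.0

    rcut2 = r_cut * r_cut
    sr6c = 1.0 / (rcut2 * rcut2 * rcut2)
    shift_unit = 4.0 * (sr6c * sr6c - sr6c)  # per unit eps

    # --- excluded volume over the neighbour list -------------------------
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        ei = eps_pair[i] if i < n else ring_eps
        ej = eps_pair[j] if j < n else ring_eps
        e = ei if ei < ej else ej
        if e <= 0.0:
            continue
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut2 or r2 <= 0.0:
            continue
        ir2 = 1.0 / r2
        ir6 = ir2 * ir2 * ir2
        ir12 = ir6 * ir6
        energies[0] += 4.0 * e * (ir12 - ir6) - e * shift_unit
        fscal = 24.0 * e * (2.0 * ir12 - ir6) * ir2
        forces[i, 0] += fscal * dx
        forces[i, 1] += fscal * dy
        forces[i, 2] += fscal * dz
        forces[j, 0] -= fscal * dx
        forces[j, 1] -= fscal * dy
        forces[j, 2] -= fscal * dz

    # --- backbone bonds --------------------------------------------------
    n_bonds = n if closed else n - 1
    for b in range(n_bonds):
        i = b
        j = (b + 1) % n
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0_bond
        energies[1] += 0.5 * k_bond * dr * dr
        fscal = -k_bond * dr / r
        forces[i, 0] += fscal * dx
        forces[i, 1] += fscal * dy
        forces[i, 2] += fscal * dz
        forces[j, 0] -= fscal * dx
        forces[j, 1] -= fscal * dy
        forces[j, 2] -= fscal * dz

    # --- side-site tethers -----------------------------------------------
    for i in range(n):
        s = n + i
        dx = pos[s, 0] - pos[i, 0]
        dy = pos[s, 1] - pos[i, 1]
        dz = pos[s, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0_side
        energies[5] += 0.5 * k_side * dr * dr
        fscal = -k_side * dr / r
        forces[s, 0] += fscal * dx
        forces[s, 1] += fscal * dy
        forces[s, 2] += fscal * dz
        forces[i, 0] -= fscal * dx
        forces[i, 1] -= fscal * dy
        forces[i, 2] -= fscal * dz

    # --- bending (Kratky-Porod) ------------------------------------------
    a_lo = 0 if closed else 1
    a_hi = n if closed else n - 1
    for a in range(a_lo, a_hi):
        im1 = (a - 1) % n
        ip1 = (a + 1) % n
        ux = pos[a, 0] - pos[im1, 0]
        uy = pos[a, 1] - pos[im1, 1]
        uz = pos[a, 2] - pos[im1, 2]
        vx = pos[ip1, 0] - pos[a, 0]
        vy = pos[ip1, 1] - pos[a, 1]
        vz = pos[ip1, 2] - pos[a, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        dot = ux * vx + uy * vy + uz * vz
        c = dot / (nu * nv)
        energies[2] += eps_bend * (1.0 - c)
        # d cos / du and / dv
        inu = 1.0 / nu
        inv = 1.0 / nv
        dcux = inu * (vx * inv - c * ux * inu)
        dcuy = inu * (vy * inv - c * uy * inu)
        dcuz = inu * (vz * inv - c * uz * inu)
        dcvx = inv * (ux * inu - c * vx * inv)
        dcvy = inv * (uy * inu - c * vy * inv)
        dcvz = inv * (uz * inu - c * vz * inv)
        forces[im1, 0] -= eps_bend * dcux
        forces[im1, 1] -= eps_bend * dcuy
        forces[im1, 2] -= eps_bend * dcuz
        forces[a, 0] += eps_bend * (dcux - dcvx)
        forces[a, 1] += eps_bend * (dcuy - dcvy)
        forces[a, 2] += eps_bend * (dcuz - dcvz)
        forces[ip1, 0] += eps_bend * dcvx
        forces[ip1, 1] += eps_bend * dcvy
        forces[ip1, 2] += eps_bend * dcvz

    # --- frame perpendicularity (side site vs central tangent) ------------
    # A single term per bead keeps the side vector perpendicular to the
    # central-difference tangent; unlike penalising both adjacent bonds
    # separately this leaves bending isotropic (no bend-direction coupling).
    if k_perp > 0.0:
        for i in range(n):
            s = n + i
            if closed:
                jp = (i + 1) % n
                jm = (i - 1) % n
            else:
                jp = i + 1 if i + 1 < n else i
                jm = i - 1 if i > 0 else i
            ux = pos[s, 0] - pos[i, 0]
            uy = pos[s, 1] - pos[i, 1]
            uz = pos[s, 2] - pos[i, 2]
            nu = math.sqrt(ux * ux + uy * uy + uz * uz)
            inu = 1.0 / nu
            wx = pos[jp, 0] - pos[jm, 0]
            wy = pos[jp, 1] - pos[jm, 1]
            wz = pos[jp, 2] - pos[jm, 2]
            nw = math.sqrt(wx * wx + wy * wy + wz * wz)
            inw = 1.0 / nw
            c = (ux * wx + uy * wy + uz * wz) * inu * inw
            energies[6] += 0.5 * k_perp * c * c
            pref = -k_perp * c
            dcux = inu * (wx * inw - c * ux * inu)
            dcuy = inu * (wy * inw - c * uy * inu)
            dcuz = inu * (wz * inw - c * uz * inu)
            dcwx = inw * (ux * inu - c * wx * inw)
            dcwy = inw * (uy * inu - c * wy * inw)
            dcwz = inw * (uz * inu - c * wz * inw)
            forces[s, 0] += pref * dcux
            forces[s, 1] += pref * dcuy
            forces[s, 2] += pref * dcuz
            forces[i, 0] -= pref * dcux
            forces[i, 1] -= pref * dcuy
            forces[i, 2] -= pref * dcuz
            forces[jp, 0] += pref * dcwx
            forces[jp, 1] += pref * dcwy
            forces[jp, 2] += pref * dcwz
            forces[jm, 0] -= pref * dcwx
            forces[jm, 1] -= pref * dcwy
            forces[jm, 2] -= pref * dcwz

    # --- torsion on the side-site ladder dihedrals ------------------------
    for b in range(n_bonds):
        i = b
        j = (b + 1) % n
        kt = k_tor[b]
        if kt == 0.0:
            continue
        s1 = n + i
        s2 = n + j
        # dihedral (side_i, bead_i, bead_j, side_j)
        b1x = pos[i, 0] - pos[s1, 0]
        b1y = pos[i, 1] - pos[s1, 1]
        b1z = pos[i, 2] - pos[s1, 2]
        b2x = pos[j, 0] - pos[i, 0]
        b2y = pos[j, 1] - pos[i, 1]
        b2z = pos[j, 2] - pos[i, 2]
        b3x = pos[s2, 0] - pos[j, 0]
        b3y = pos[s2, 1] - pos[j, 1]
        b3z = pos[s2, 2] - pos[j, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2sq = b2x * b2x + b2y * b2y + b2z * b2z
        nb2 = math.sqrt(b2sq)
        if n1sq < 1e-14 or n2sq < 1e-14:
            continue
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        y = (mx * b2x + my * b2y + mz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = math.atan2(y, x)
        energies[3] += 0.5 * kt * phi * phi
        dvdphi = kt * phi
        # gradients of phi
        f1 = -nb2 / n1sq
        g1x = f1 * n1x
        g1y = f1 * n1y
        g1z = f1 * n1z
        f4 = nb2 / n2sq
        g4x = f4 * n2x
        g4y = f4 * n2y
        g4z = f4 * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        g2x = -(1.0 + d12) * g1x + d32 * g4x
        g2y = -(1.0 + d12) * g1y + d32 * g4y
        g2z = -(1.0 + d12) * g1z + d32 * g4z
        g3x = d12 * g1x - (1.0 + d32) * g4x
        g3y = d12 * g1y - (1.0 + d32) * g4y
        g3z = d12 * g1z - (1.0 + d32) * g4z
        forces[s1, 0] -= dvdphi * g1x
        forces[s1, 1] -= dvdphi * g1y
        forces[s1, 2] -= dvdphi * g1z
        forces[i, 0] -= dvdphi * g2x
        forces[i, 1] -= dvdphi * g2y
        forces[i, 2] -= dvdphi * g2z
        forces[j, 0] -= dvdphi * g3x
        forces[j, 1] -= dvdphi * g3y
        forces[j, 2] -= dvdphi * g3z
        forces[s2, 0] -= dvdphi * g4x
        forces[s2, 1] -= dvdphi * g4y
        forces[s2, 2] -= dvdphi * g4z

    # --- motor couples -----------------------------------------------------
    # Each motor applies an external axial torque (reaction absorbed by the
    # implicit solvent) as a pure force couple between a motor bead and its
    # side site; the torque component about the motor bond axis is exactly
    # mot_c, winding twist into the fibre on the gene-body side.
    n_motors = mot_bead.shape[0]
    for m in range(n_motors):
        bd = mot_bead[m]
        ai = mot_ax_i[m]
        aj = mot_ax_j[m]
        c = mot_c[m]
        tx = pos[aj, 0] - pos[ai, 0]
        ty = pos[aj, 1] - pos[ai, 1]
        tz = pos[aj, 2] - pos[ai, 2]
        tn = math.sqrt(tx * tx + ty * ty + tz * tz)
        tx /= tn
        ty /= tn
        tz /= tn
        s = n + bd
        ux = pos[s, 0] - pos[bd, 0]
        uy = pos[s, 1] - pos[bd, 1]
        uz = pos[s, 2] - pos[bd, 2]
        udt = ux * tx + uy * ty + uz * tz
        up2 = ux * ux + uy * uy + uz * uz - udt * udt
        if up2 < 1e-8:
            continue  # side site degenerate with the axis: no lever arm
        pref = c / up2
        fx = pref * (ty * uz - tz * uy)
        fy = pref * (tz * ux - tx * uz)
        fz = pref * (tx * uy - ty * ux)
        forces[s, 0] += fx
        forces[s, 1] += fy
        forces[s, 2] += fz
        forces[bd, 0] -= fx
        forces[bd, 1] -= fy
        forces[bd, 2] -= fz

    # --- ring anchor restraints -------------------------------------------
    for r in range(n_rings):
        a = ring_anchor[r]
        base = 2 * n + r * RING_BEADS
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for k in range(RING_BEADS):
            cx += pos[base + k, 0]
            cy += pos[base + k, 1]
            cz += pos[base + k, 2]
        cx /= RING_BEADS
        cy /= RING_BEADS
        cz /= RING_BEADS
        dx = cx - pos[a, 0]
        dy = cy - pos[a, 1]
        dz = cz - pos[a, 2]
        energies[7] += 0.5 * k_anchor * (dx * dx + dy * dy + dz * dz)
        f_ring_centers[r, 0] = -k_anchor * dx
        f_ring_centers[r, 1] = -k_anchor * dy
        f_ring_centers[r, 2] = -k_anchor * dz
        forces[a, 0] += k_anchor * dx
        forces[a, 1] += k_anchor * dy
        forces[a, 2] += k_anchor * dz

    return 0


# ---------------------------------------------------------------------------
# Langevin propagation (BAOAB for chain sites, Brownian rigid-body for rings)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def run_langevin(
    pos,
    vel,
    n,
    closed,
    box,
    eps_pair,
    r_cut,
    k_bond,
    r0_bond,
    eps_bend,
    k_tor,
    mot_bead,
    mot_ax_i,
    mot_ax_j,
    mot_c,
    k_side,
    r0_side,
    k_perp,
    ring_eps,
    ring_anchor,
    k_anchor,
    ring_body,
    ring_orient,
    gamma_ring_t,
    gamma_ring_r,
    dt,
    gamma,
    kT,
    n_steps,
    report_every,
    seed,
    rebuild_every,
    skin,
    frames,
    rg_out,
    en_out,
):
    """Propagate the system; fill per-report frames, Rg and energy terms.

    Chain sites (beads + side sites, unit mass) follow BAOAB Langevin
    dynamics; cohesin rings move as overdamped rigid bodies (Euler-Maruyama
    on centre position and orientation).  Returns a status code.
    """
    np.random.seed(seed)
    n_free = 2 * n
    n_rings = ring_anchor.shape[0]
    n_ring_sites = n_rings * RING_BEADS
    n_sites = n_free + n_ring_sites

    forces = np.zeros((n_sites, 3))
    energies = np.zeros(8)
    f_rc = np.zeros((n_rings, 3))
    max_pairs = 160 * (n + n_ring_sites) + 1024
    pairs = np.empty((max_pairs, 2), dtype=np.int64)

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1))
    noise_chunk = 256
    noise = np.empty((noise_chunk * n_free, 3))
    noise_at = noise_chunk * n_free  # force refill on first use

    npairs = build_pairs(pos, n, closed, n_ring_sites, box, r_cut + skin, pairs)
    if npairs < 0:
        return STATUS_PAIR_OVERFLOW
    compute_forces(
        pos, n, closed, box, eps_pair, r_cut, k_bond, r0_bond, eps_bend,
        k_tor, mot_bead, mot_ax_i, mot_ax_j, mot_c, k_side, r0_side, k_perp,
        ring_eps, ring_anchor, k_anchor, pairs, npairs, forces, energies, f_rc,
    )

    # report index 0: initial state
    rep = 0
    for i in range(n_sites):
        frames[rep, i, 0] = pos[i, 0]
        frames[rep, i, 1] = pos[i, 1]
        frames[rep, i, 2] = pos[i, 2]
    rg_out[rep] = _radius_of_gyration(pos, n)
    for k in range(8):
        en_out[rep, k] = energies[k]

    max_step2 = 0.25  # abort threshold on per-step displacement (0.5 sigma)^2

    for step in range(1, n_steps + 1):
        # B
        half = 0.5 * dt
        for i in range(n_free):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
        # A
        for i in range(n_free):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # O
        if gamma > 0.0:
            if noise_at + n_free > noise_chunk * n_free:
                noise = np.random.standard_normal((noise_chunk * n_free, 3))
                noise_at = 0
            for i in range(n_free):
                k = noise_at + i
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[k, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[k, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[k, 2]
            noise_at += n_free
        # A
        for i in range(n_free):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]

        if step % rebuild_every == 0:
            npairs = build_pairs(
                pos, n, closed, n_ring_sites, box, r_cut + skin, pairs
            )
            if npairs < 0:
                return STATUS_PAIR_OVERFLOW

        compute_forces(
            pos, n, closed, box, eps_pair, r_cut, k_bond, r0_bond, eps_bend,
            k_tor, mot_bead, mot_ax_i, mot_ax_j, mot_c, k_side, r0_side,
            k_perp, ring_eps, ring_anchor, k_anchor, pairs, npairs, forces,
            energies, f_rc,
        )
        # B
        for i in range(n_free):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            # blow-up check on the full-step displacement scale
            v2 = (
                vel[i, 0] * vel[i, 0]
                + vel[i, 1] * vel[i, 1]
                + vel[i, 2] * vel[i, 2]
            )
            if v2 * dt * dt > max_step2:
                return STATUS_BLOWUP

        # rigid rings: overdamped Brownian update from current forces
        if n_rings > 0:
            rnoise = np.random.standard_normal((n_rings, 6))
            sig_t = math.sqrt(2.0 * kT * dt / gamma_ring_t)
            sig_r = math.sqrt(2.0 * kT * dt / gamma_ring_r)
            for r in range(n_rings):
                base = n_free + r * RING_BEADS
                cx = 0.0
                cy = 0.0
                cz = 0.0
                for k in range(RING_BEADS):
                    cx += pos[base + k, 0]
                    cy += pos[base + k, 1]
                    cz += pos[base + k, 2]
                cx /= RING_BEADS
                cy /= RING_BEADS
                cz /= RING_BEADS
                fx = f_rc[r, 0]
                fy = f_rc[r, 1]
                fz = f_rc[r, 2]
                tx = 0.0
                ty = 0.0
                tz = 0.0
                for k in range(RING_BEADS):
                    bfx = forces[base + k, 0]
                    bfy = forces[base + k, 1]
                    bfz = forces[base + k, 2]
                    fx += bfx
                    fy += bfy
                    fz += bfz
                    rx = pos[base + k, 0] - cx
                    ry = pos[base + k, 1] - cy
                    rz = pos[base + k, 2] - cz
                    tx += ry * bfz - rz * bfy
                    ty += rz * bfx - rx * bfz
                    tz += rx * bfy - ry * bfx
                ncx = cx + fx / gamma_ring_t * dt + sig_t * rnoise[r, 0]
                ncy = cy + fy / gamma_ring_t * dt + sig_t * rnoise[r, 1]
                ncz = cz + fz / gamma_ring_t * dt + sig_t * rnoise[r, 2]
                wx = tx / gamma_ring_r * dt + sig_r * rnoise[r, 3]
                wy = ty / gamma_ring_r * dt + sig_r * rnoise[r, 4]
                wz = tz / gamma_ring_r * dt + sig_r * rnoise[r, 5]
                _rotate_orientation(ring_orient, r, wx, wy, wz)
                for k in range(RING_BEADS):
                    bx = ring_body[k, 0]
                    by = ring_body[k, 1]
                    bz = ring_body[k, 2]
                    pos[base + k, 0] = (
                        ncx
                        + ring_orient[r, 0, 0] * bx
                        + ring_orient[r, 0, 1] * by
                        + ring_orient[r, 0, 2] * bz
                    )
                    pos[base + k, 1] = (
                        ncy
                        + ring_orient[r, 1, 0] * bx
                        + ring_orient[r, 1, 1] * by
                        + ring_orient[r, 1, 2] * bz
                    )
                    pos[base + k, 2] = (
                        ncz
                        + ring_orient[r, 2, 0] * bx
                        + ring_orient[r, 2, 1] * by
                        + ring_orient[r, 2, 2] * bz
                    )

        if step % report_every == 0:
            rep += 1
            for i in range(n_sites):
                frames[rep, i, 0] = pos[i, 0]
                frames[rep, i, 1] = pos[i, 1]
                frames[rep, i, 2] = pos[i, 2]
            rg_out[rep] = _radius_of_gyration(pos, n)
            for k in range(8):
                en_out[rep, k] = energies[k]

    return STATUS_OK


@njit(cache=True)
def _rotate_orientation(ring_orient, r, wx, wy, wz):
    """Left-multiply orientation r by the rotation with axis-angle (wx,wy,wz)."""
    theta = math.sqrt(wx * wx + wy * wy + wz * wz)
    if theta < 1e-12:
        return
    ux = wx / theta
    uy = wy / theta
    uz = wz / theta
    c = math.cos(theta)
    s = math.sin(theta)
    omc = 1.0 - c
    # rotation matrix R
    r00 = c + ux * ux * omc
    r01 = ux * uy * omc - uz * s
    r02 = ux * uz * omc + uy * s
    r10 = uy * ux * omc + uz * s
    r11 = c + uy * uy * omc
    r12 = uy * uz * omc - ux * s
    r20 = uz * ux * omc - uy * s
    r21 = uz * uy * omc + ux * s
    r22 = c + uz * uz * omc
    for col in range(3):
        a0 = ring_orient[r, 0, col]
        a1 = ring_orient[r, 1, col]
        a2 = ring_orient[r, 2, col]
        ring_orient[r, 0, col] = r00 * a0 + r01 * a1 + r02 * a2
        ring_orient[r, 1, col] = r10 * a0 + r11 * a1 + r12 * a2
        ring_orient[r, 2, col] = r20 * a0 + r21 * a1 + r22 * a2


@njit(cache=True)
def _radius_of_gyration(pos, n):
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(n):
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= n
    cy /= n
    cz /= n
    s = 0.0
    for i in range(n):
        dx = pos[i, 0] - cx
        dy = pos[i, 1] - cy
        dz = pos[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return math.sqrt(s / n)


# ---------------------------------------------------------------------------
# topology sums
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _gauss_pair(
    p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z, p4x, p4y, p4z
) -> float:
    """Signed solid angle subtended by segments (p1,p2) and (p3,p4).

    Pairwise term of the discretised Gauss double integral (the
    Klenin-Langowski quadrilateral construction); the writhe contribution of
    the unordered pair is this value / (2 pi).
    """
    r13x = p3x - p1x
    r13y = p3y - p1y
    r13z = p3z - p1z
    r14x = p4x - p1x
    r14y = p4y - p1y
    r14z = p4z - p1z
    r23x = p3x - p2x
    r23y = p3y - p2y
    r23z = p3z - p2z
    r24x = p4x - p2x
    r24y = p4y - p2y
    r24z = p4z - p2z
    # face normals of the tetrahedron
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x
    m1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if m1 < 1e-12 or m2 < 1e-12 or m3 < 1e-12 or m4 < 1e-12:
        return 0.0
    n1x /= m1
    n1y /= m1
    n1z /= m1
    n2x /= m2
    n2y /= m2
    n2z /= m2
    n3x /= m3
    n3y /= m3
    n3z /= m3
    n4x /= m4
    n4y /= m4
    n4z /= m4
    d12 = n1x * n2x + n1y * n2y + n1z * n2z
    d23 = n2x * n3x + n2y * n3y + n2z * n3z
    d34 = n3x * n4x + n3y * n4y + n3z * n4z
    d41 = n4x * n1x + n4y * n1y + n4z * n1z
    if d12 > 1.0:
        d12 = 1.0
    elif d12 < -1.0:
        d12 = -1.0
    if d23 > 1.0:
        d23 = 1.0
    elif d23 < -1.0:
        d23 = -1.0
    if d34 > 1.0:
        d34 = 1.0
    elif d34 < -1.0:
        d34 = -1.0
    if d41 > 1.0:
        d41 = 1.0
    elif d41 < -1.0:
        d41 = -1.0
    omega = math.asin(d12) + math.asin(d23) + math.asin(d34) + math.asin(d41)
    # sign from (r34 x r12) . r13
    r34x = p4x - p3x
    r34y = p4y - p3y
    r34z = p4z - p3z
    r12x = p2x - p1x
    r12y = p2y - p1y
    r12z = p2z - p1z
    cxx = r34y * r12z - r34z * r12y
    cxy = r34z * r12x - r34x * r12z
    cxz = r34x * r12y - r34y * r12x
    sgn = cxx * r13x + cxy * r13y + cxz * r13z
    if sgn > 0.0:
        return omega
    elif sgn < 0.0:
        return -omega
    return 0.0


@njit(cache=True)
def writhe_range(pos, i0, i1, closed):
    """Gauss-sum writhe of beads [i0, i1) of the chain stored in ``pos``.

    ``closed`` may only be set when the range covers the whole chain; it adds
    the closure segment and skips the wrap-adjacent pair.
    """
    m = i1 - i0
    n_seg = m if closed else m - 1
    total = 0.0
    for a in range(n_seg):
        ia = i0 + a
        ja = i0 + (a + 1) % m
        for b in range(a + 2, n_seg):
            if closed and a == 0 and b == n_seg - 1:
                continue
            ib = i0 + b
            jb = i0 + (b + 1) % m
            total += _gauss_pair(
                pos[ia, 0], pos[ia, 1], pos[ia, 2],
                pos[ja, 0], pos[ja, 1], pos[ja, 2],
                pos[ib, 0], pos[ib, 1], pos[ib, 2],
                pos[jb, 0], pos[jb, 1], pos[jb, 2],
            )
    return total / (2.0 * math.pi)


@njit(cache=True)
def twist_sum(pos, n, closed):
    """Total twist (turns) of the side-site ladder: sum of wrapped dihedrals."""
    n_bonds = n if closed else n - 1
    total = 0.0
    for b in range(n_bonds):
        i = b
        j = (b + 1) % n
        phi = dihedral_angle(
            pos[n + i, 0], pos[n + i, 1], pos[n + i, 2],
            pos[i, 0], pos[i, 1], pos[i, 2],
            pos[j, 0], pos[j, 1], pos[j, 2],
            pos[n + j, 0], pos[n + j, 1], pos[n + j, 2],
        )
        total += phi
    return total / (2.0 * math.pi)


@njit(cache=True)
def twist_sum_pt(pos, n, closed):
    """Exact polygonal ribbon twist (turns): parallel-transport convention.

    Projects each vertex side vector onto the plane of its outgoing bond,
    parallel-transports it across each vertex bend, and accumulates the
    residual rotation about the bond axis.  Together with the Gauss-sum
    writhe this satisfies the Calugareanu-White identity Lk = Tw + Wr exactly
    for closed ribbons (up to roundoff), unlike the raw dihedral sum which
    carries O(bend^2) discretisation error.
    """
    n_bonds = n if closed else n - 1
    n_junc = n_bonds if closed else n_bonds - 1
    total = 0.0
    for v in range(n_junc):
        b0 = v
        b1 = (v + 1) % n_bonds
        i0 = b0
        j0 = (b0 + 1) % n
        i1 = b1
        j1 = (b1 + 1) % n
        t0x = pos[j0, 0] - pos[i0, 0]
        t0y = pos[j0, 1] - pos[i0, 1]
        t0z = pos[j0, 2] - pos[i0, 2]
        m = math.sqrt(t0x * t0x + t0y * t0y + t0z * t0z)
        t0x /= m
        t0y /= m
        t0z /= m
        t1x = pos[j1, 0] - pos[i1, 0]
        t1y = pos[j1, 1] - pos[i1, 1]
        t1z = pos[j1, 2] - pos[i1, 2]
        m = math.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
        t1x /= m
        t1y /= m
        t1z /= m
        # frame vectors of the two bonds, from their starting vertices
        ux = pos[n + i0, 0] - pos[i0, 0]
        uy = pos[n + i0, 1] - pos[i0, 1]
        uz = pos[n + i0, 2] - pos[i0, 2]
        d = ux * t0x + uy * t0y + uz * t0z
        a0x = ux - d * t0x
        a0y = uy - d * t0y
        a0z = uz - d * t0z
        ux = pos[n + i1, 0] - pos[i1, 0]
        uy = pos[n + i1, 1] - pos[i1, 1]
        uz = pos[n + i1, 2] - pos[i1, 2]
        d = ux * t1x + uy * t1y + uz * t1z
        a1x = ux - d * t1x
        a1y = uy - d * t1y
        a1z = uz - d * t1z
        # parallel transport a0 from t0 to t1: rotate about t0 x t1
        axx = t0y * t1z - t0z * t1y
        axy = t0z * t1x - t0x * t1z
        axz = t0x * t1y - t0y * t1x
        s2 = axx * axx + axy * axy + axz * axz
        if s2 > 1e-24:
            c = t0x * t1x + t0y * t1y + t0z * t1z
            # Rodrigues rotation with axis (axx,axy,axz) (norm = sin)
            # and angle with cos = c, sin = |axis|
            s = math.sqrt(s2)
            kx = axx / s
            ky = axy / s
            kz = axz / s
            kdota = kx * a0x + ky * a0y + kz * a0z
            cxx = ky * a0z - kz * a0y
            cxy = kz * a0x - kx * a0z
            cxz = kx * a0y - ky * a0x
            a0x = a0x * c + cxx * s + kx * kdota * (1.0 - c)
            a0y = a0y * c + cxy * s + ky * kdota * (1.0 - c)
            a0z = a0z * c + cxz * s + kz * kdota * (1.0 - c)
        # signed angle from transported a0 to a1 about t1
        cxx = a0y * a1z - a0z * a1y
        cxy = a0z * a1x - a0x * a1z
        cxz = a0x * a1y - a0y * a1x
        y = cxx * t1x + cxy * t1y + cxz * t1z
        x = a0x * a1x + a0y * a1y + a0z * a1z
        total += math.atan2(y, x)
    return total / (2.0 * math.pi)


@njit(cache=True)
def contact_counts(frames, n, box, cutoff, counts):
    """Accumulate symmetric bead-bead contact counts over trajectory frames."""
    cutoff2 = cutoff * cutoff
    n_frames = frames.shape[0]
    for f in range(n_frames):
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(frames[f, i, 0] - frames[f, j, 0], box)
                if dx * dx > cutoff2:
                    continue
                dy = _min_image(frames[f, i, 1] - frames[f, j, 1], box)
                dz = _min_image(frames[f, i, 2] - frames[f, j, 2], box)
                if dx * dx + dy * dy + dz * dz <= cutoff2:
                    counts[i, j] += 1
                    counts[j, i] += 1
    return 0
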
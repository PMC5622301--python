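"""Topological observables: writhe, twist, linking number, Lp, passages.

Writhe is the discretised Gauss double integral over non-adjacent segment
pairs (the Klenin-Langowski pairwise solid-angle sum); per-domain writhe
restricts both segments to the domain's bead range.  Twist is the sum of the
signed side-site-ladder dihedrals in turns.  For a torsionally closed ribbon
(no swivels) the linking number Lk = Tw + Wr is conserved between
intersegmental passage events, and each passage changes it by +-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .dynamics import Trajectory
from .model import FiberSystem
from .units import SIGMA_NM

__all__ = [
    "writhe",
    "twist",
    "linking_number",
    "persistence_length",
    "detect_passage_events",
    "plectoneme_passage_configs",
    "PassageEvent",
    "TopologySeries",
    "compute_topology_series",
]


def writhe(
    positions: np.ndarray,
    closed: bool = False,
    bead_range: tuple[int, int] | None = None,
) -> float:
    """Gauss-sum writhe (in turns) of an ordered bead path.

    Open chains use the open Gauss sum without artificial closure.
    ``bead_range`` restricts the sum to a half-open bead range (per-domain
    writhe; cross-domain terms excluded).
    """
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    i0, i1 = bead_range if bead_range is not None else (0, pos.shape[0])
    if i1 - i0 < 4:
        raise ValueError("need at least 4 beads")
    seg = pos[i0:i1] if not closed else pos
    if np.any(np.linalg.norm(np.diff(seg, axis=0), axis=1) < 1e-9):
        raise ValueError("coincident consecutive beads")
    if closed and bead_range is not None and (i1 - i0) != pos.shape[0]:
        raise ValueError("closed writhe requires the full chain range")
    return float(K.writhe_range(pos, i0, i1, closed))


def twist(
    side_sites: np.ndarray,
    positions: np.ndarray,
    closed: bool = False,
    method: str = "dihedral",
) -> float:
    """Total twist in turns of the side-site ladder.

    ``method="dihedral"``: sum of the wrapped ladder dihedrals / 2 pi (the
    quantity the torsion potential acts on).  ``method="pt"``: the exact
    polygonal ribbon twist in the parallel-transport convention, which
    satisfies Lk = Tw + Wr identically on closed ribbons; the two agree to
    O(bend^2) per joint.
    """
    pos = np.asarray(positions, float)
    side = np.asarray(side_sites, float)
    if pos.shape != side.shape:
        raise ValueError("side_sites and positions must have the same shape")
    stacked = np.vstack([pos, side])
    if method == "dihedral":
        return float(K.twist_sum(stacked, pos.shape[0], closed))
    if method == "pt":
        return float(K.twist_sum_pt(stacked, pos.shape[0], closed))
    raise ValueError(f"unknown twist method {method!r}")


def linking_number(
    system: FiberSystem,
    positions: np.ndarray | None = None,
    side_sites: np.ndarray | None = None,
) -> float:
    """Lk = Tw + Wr of a torsionally closed ribbon.

    Undefined (error) for open chains or chains containing swivel bonds,
    where twist can dissipate freely.
    """
    if not system.closed:
        raise ValueError("linking number undefined for an open chain")
    if system.swivel_bonds:
        raise ValueError("linking number undefined with swivel bonds present")
    pos = system.positions if positions is None else np.asarray(positions, float)
    side = system.side_sites if side_sites is None else np.asarray(side_sites, float)
    # parallel-transport twist: the exact ribbon twist for which
    # Lk = Tw + Wr is an identity on the polygon
    return twist(side, pos, closed=True, method="pt") + writhe(pos, closed=True)


def tangent_correlation(bead_frames: np.ndarray, max_sep: int) -> np.ndarray:
    """Mean tangent-tangent correlation <t_i . t_{i+s}> for s = 0..max_sep."""
    frames = np.asarray(bead_frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    t = np.diff(frames, axis=1)
    t /= np.linalg.norm(t, axis=2, keepdims=True)
    nb = t.shape[1]
    corr = np.empty(max_sep + 1)
    for s in range(max_sep + 1):
        corr[s] = np.mean(np.einsum("fid,fid->fi", t[:, : nb - s], t[:, s:]))
    return corr


def persistence_length(
    trajectory_or_frames: Trajectory | np.ndarray,
    bond_length_nm: float = SIGMA_NM,
    max_sep_nm: float = 150.0,
) -> float:
    """Persistence length (nm) from tangent-correlation decay of a passive chain.

    Fits ``<t_i . t_{i+s}> = exp(-s b / Lp)`` by weighted log-linear
    regression over separations up to ``max_sep_nm``.
    """
    if isinstance(trajectory_or_frames, Trajectory):
        frames = trajectory_or_frames.bead_frames()
    else:
        frames = np.asarray(trajectory_or_frames, float)
    max_sep = max(2, int(max_sep_nm / bond_length_nm))
    max_sep = min(max_sep, (frames.shape[-2] - 1) - 1)
    corr = tangent_correlation(frames, max_sep)
    s = np.arange(max_sep + 1)
    keep = corr > 0.02
    # weights ~ corr^2: the delta-method variance of log(corr) grows as
    # 1/corr^2, so this is the standard weighting for a log-linear decay fit
    slope = np.polyfit(
        s[keep], np.log(corr[keep]), 1, w=corr[keep]
    )[0]
    if slope >= 0:
        raise ValueError("tangent correlations do not decay; chain too short?")
    return float(-bond_length_nm / slope)


def plectoneme_passage_configs(
    separation: float = 1.1,
    n_beads: int = 260,
    arm: float = 6.0,
    reach: float = 28.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed curves before/after one intersegmental passage.

    Builds a closed ribbon with a single close interwound crossing: a
    straight segment along x passing ``separation/2`` above a straight
    segment along y, joined by wide return loops.  The "after" configuration
    displaces the upper segment through the lower one along their common
    normal, ending ``separation`` below it, with all other beads fixed.
    With the twist held fixed, the Gauss-sum writhe changes by exactly the
    +-2 of one duplex passage (up to the small far-field contribution of the
    return loops).
    """
    from scipy.interpolate import splev, splprep

    h = separation / 2.0
    ctrl = np.array(
        [
            [-arm, 0.0, h],
            [0.0, 0.0, h],
            [arm, 0.0, h],
            [reach, reach * 0.7, 5.0],
            [0.0, reach * 0.85, -h],
            [0.0, arm, -h],
            [0.0, 0.0, -h],
            [0.0, -arm, -h],
            [0.0, -reach * 0.85, -h],
            [-reach, -reach * 0.7, 5.0],
        ]
    ).T
    tck, _ = splprep(ctrl, s=0, per=True, k=3)
    t = np.linspace(0.0, 1.0, n_beads, endpoint=False)
    before = np.column_stack(splev(t, tck))
    after = before.copy()
    # displace the upper segment through the lower, tapering to the ends
    on_a = (np.abs(before[:, 1]) < 1.2) & (before[:, 2] > 0.0) & (
        np.abs(before[:, 0]) < arm
    )
    x = np.abs(before[on_a, 0])
    flat = 0.5 * arm  # full displacement near the crossing, cosine shoulders
    taper = np.where(
        x < flat,
        1.0,
        0.5 * (1.0 + np.cos(np.pi * (x - flat) / (arm - flat))),
    )
    after[on_a, 2] -= 2.0 * separation * taper
    return before, after


@dataclass
class PassageEvent:
    """One detected intersegmental passage (abrupt writhe jump)."""

    step: int
    domain: int
    delta_wr: float


def detect_passage_events(
    writhe_series: np.ndarray,
    threshold: float = 1.5,
    steps: np.ndarray | None = None,
    domains: list[int] | None = None,
) -> list[PassageEvent]:
    """Find abrupt writhe changes |dWr| >= threshold between reports.

    ``writhe_series`` is (F,) or (F, n_domains).  An intersegmental passage
    changes the writhe by ~2 within one sampling interval, well above the
    thermal fluctuation scale; the default threshold 1.5 sits between the
    two.
    """
    w = np.atleast_2d(np.asarray(writhe_series, float).T).T
    if steps is None:
        steps = np.arange(w.shape[0])
    if domains is None:
        domains = list(range(w.shape[1]))
    events = []
    dw = np.diff(w, axis=0)
    hits = np.nonzero(np.abs(dw) >= threshold)
    for f, d in zip(*hits):
        events.append(
            PassageEvent(step=int(steps[f + 1]), domain=domains[d], delta_wr=float(dw[f, d]))
        )
    return events


@dataclass
class TopologySeries:
    """Per-frame topology of one trajectory (turns; Rg in nm)."""

    steps: np.ndarray
    writhe_total: np.ndarray
    writhe_domains: np.ndarray  # (F, n_domains)
    twist: np.ndarray
    lk: np.ndarray | None  # closed swivel-free ribbons only
    rg_nm: np.ndarray
    events: list[PassageEvent]


def compute_topology_series(
    traj: Trajectory,
    system: FiberSystem,
    include_motor_beads: bool = True,
    passage_threshold: float = 1.5,
) -> TopologySeries:
    """Writhe/twist/Lk series and passage events for a trajectory."""
    beads = traj.bead_frames()
    sides = traj.side_frames()
    nf = traj.n_frames
    ranges = (
        system.layout.writhe_ranges(include_motor_beads) if system.layout else []
    )
    wr_tot = np.empty(nf)
    tw = np.empty(nf)
    wr_dom = np.empty((nf, len(ranges)))
    for f in range(nf):
        wr_tot[f] = K.writhe_range(beads[f], 0, traj.n_beads, traj.closed)
        tw[f] = K.twist_sum(traj.frames[f], traj.n_beads, traj.closed)
        for d, (a, b) in enumerate(ranges):
            wr_dom[f, d] = K.writhe_range(beads[f], a, b, False)
    lk = tw + wr_tot if (traj.closed and not system.swivel_bonds) else None
    series = wr_dom if ranges else wr_tot
    events = detect_passage_events(series, passage_threshold, steps=traj.steps)
    return TopologySeries(
        steps=traj.steps.copy(),
        writhe_total=wr_tot,
        writhe_domains=wr_dom,
        twist=tw,
        lk=lk,
        rg_nm=traj.rg * SIGMA_NM,
        events=events,
    )
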
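"""Langevin dynamics of fibre systems under periodic boundary conditions.

Chain sites follow BAOAB-splitting Langevin dynamics at temperature kT with
unit mass and friction; rigid cohesin rings move by overdamped Brownian
rigid-body updates.  Positions are integrated unwrapped (topology measures
need continuous coordinates); the periodic box enters through minimum-image
non-bonded interactions.

Replica management mirrors the study design: several independent copies per
condition, each pre-thermalized and then evolved for a multiple of its
Rg autocorrelation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .forcefield import ForceFieldParams, PackedSystem
from .model import FiberSystem, RING_BEADS

__all__ = [
    "IntegratorSettings",
    "Trajectory",
    "Simulation",
    "IntegratorBlowupError",
    "langevin_step",
    "run_simulation",
    "run_scenario_replicas",
    "autocorrelation_time",
    "physical_time_per_step",
]


class IntegratorBlowupError(RuntimeError):
    """A site moved more than 0.5 sigma in one step: the run is unstable."""


@dataclass
class IntegratorSettings:
    """Langevin integrator and replica configuration (reduced units)."""

    dt: float = 1e-3
    gamma: float = 1.0
    kT: float = 1.0
    n_steps: int = 100_000
    report_every: int = 1000
    seed: int = 0
    n_replicas: int = 5
    thermalization_steps: int = 0
    rebuild_every: int = 10
    skin: float = 0.5

    def __post_init__(self) -> None:
        # stability bound for the stiffest mode (side tethers, k ~ 8000/m=1)
        if self.dt * max(self.gamma, 90.0) > 2.0:
            raise ValueError(f"dt = {self.dt} unstable for the stiff bond modes")
        if self.report_every < 1 or self.n_steps < 0:
            raise ValueError("bad step counts")

    def replica_seeds(self) -> list[int]:
        """Distinct per-replica seeds derived from the base seed (< 2^31)."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s) for s in ss.generate_state(self.n_replicas) % (2**31 - 1)]


@dataclass
class Trajectory:
    """Per-report frames and series from one replica.

    ``frames`` hold unwrapped coordinates of all sites (beads, side sites,
    ring beads); topology series are attached by
    :func:`supercoilsim.topology.compute_topology_series`.
    """

    steps: np.ndarray  # (F,) step index of each frame
    frames: np.ndarray  # (F, n_sites, 3)
    rg: np.ndarray  # (F,) backbone radius of gyration, sigma
    energies: np.ndarray  # (F, 8) term breakdown per frame
    n_beads: int
    closed: bool
    box: float
    dt: float
    seed: int
    thermalized: bool = False
    tau_ac: float | None = None  # Rg autocorrelation time, in report intervals
    converged: bool = True

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def bead_frames(self) -> np.ndarray:
        return self.frames[:, : self.n_beads]

    def side_frames(self) -> np.ndarray:
        return self.frames[:, self.n_beads : 2 * self.n_beads]


class Simulation:
    """Mutable integration state bound to one system and parameter set."""

    def __init__(
        self,
        system: FiberSystem,
        params: ForceFieldParams | None = None,
        settings: IntegratorSettings | None = None,
    ):
        self.system = system
        self.params = params or ForceFieldParams()
        self.settings = settings or IntegratorSettings()
        self.packed = PackedSystem(system, self.params)
        self.positions = system.sites().astype(float)
        self.velocities = np.zeros_like(self.positions)
        self.step_count = 0

    def run(
        self, n_steps: int, report_every: int | None = None, seed: int | None = None
    ) -> Trajectory:
        """Advance by ``n_steps``, returning the per-report trajectory.

        The initial state is always frame 0.  State (positions, velocities)
        persists across calls, so thermalization and production can be
        separate calls.
        """
        st = self.settings
        report_every = report_every or st.report_every
        seed = st.seed if seed is None else seed
        p = self.packed
        n_reports = n_steps // report_every + 1
        frames = np.empty((n_reports, p.n_sites, 3))
        rg = np.empty(n_reports)
        en = np.empty((n_reports, 8))
        status = K.run_langevin(
            self.positions,
            self.velocities,
            p.n,
            p.closed,
            p.box,
            p.eps_pair,
            self.params.r_cut,
            self.params.k_bond,
            self.params.r0_bond,
            self.params.eps_bend,
            p.k_tor,
            p.mot_bead,
            p.mot_ax_i,
            p.mot_ax_j,
            p.mot_c,
            self.params.k_side,
            self.params.r0_side,
            self.params.k_perp,
            self.params.ring_eps,
            p.ring_anchor,
            self.params.k_anchor,
            p.ring_body,
            p.ring_orient,
            p.gamma_ring_t,
            p.gamma_ring_r,
            st.dt,
            st.gamma,
            st.kT,
            n_steps,
            report_every,
            int(seed) % (2**31 - 1),
            st.rebuild_every,
            st.skin,
            frames,
            rg,
            en,
        )
        if status == K.STATUS_BLOWUP:
            raise IntegratorBlowupError(
                f"displacement exceeded 0.5 sigma/step at step <= {self.step_count + n_steps} "
                f"(dt={st.dt}, n_beads={p.n}); reduce dt"
            )
        if status == K.STATUS_PAIR_OVERFLOW:
            raise RuntimeError("neighbour-list overflow: system collapsed?")
        self.step_count += n_steps
        return Trajectory(
            steps=np.arange(n_reports) * report_every,
            frames=frames,
            rg=rg,
            energies=en,
            n_beads=p.n,
            closed=p.closed,
            box=p.box,
            dt=st.dt,
            seed=int(seed),
        )


def langevin_step(
    sim: Simulation, n_steps: int = 1, seed: int | None = None
) -> Simulation:
    """Advance a simulation by ``n_steps`` single Langevin updates in place."""
    sim.run(n_steps, report_every=max(n_steps, 1), seed=seed)
    return sim


def run_simulation(
    system: FiberSystem,
    params: ForceFieldParams | None = None,
    settings: IntegratorSettings | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Convenience wrapper: fresh state, thermalization + production run."""
    settings = settings or IntegratorSettings()
    sim = Simulation(system, params, settings)
    if settings.thermalization_steps:
        sim.run(
            settings.thermalization_steps,
            report_every=settings.thermalization_steps,
            seed=(seed if seed is not None else settings.seed) + 7,
        )
    traj = sim.run(settings.n_steps, seed=seed)
    traj.thermalized = settings.thermalization_steps > 0
    return traj


def run_scenario_replicas(
    system_factory,
    settings: IntegratorSettings,
    params: ForceFieldParams | None = None,
    tau_multiplier: float = 8.0,
    max_production_steps: int | None = None,
    auto_length: bool = False,
) -> list[Trajectory]:
    """Run independent replicas of a scenario.

    ``system_factory(replica_index, seed)`` must return a fresh
    :class:`FiberSystem`.  Each replica is thermalized
    (``settings.thermalization_steps``), then evolved for
    ``settings.n_steps`` production steps — or, with ``auto_length``, for
    ``tau_multiplier`` times the Rg autocorrelation time measured on a pilot
    segment (capped at ``max_production_steps``).  Replicas get distinct
    seeds; a replica whose autocorrelation time cannot be estimated is
    flagged ``converged=False``.
    """
    trajectories = []
    for rep, seed in enumerate(settings.replica_seeds()):
        system = system_factory(rep, seed)
        sim = Simulation(system, params, settings)
        if settings.thermalization_steps:
            sim.run(
                settings.thermalization_steps,
                report_every=settings.thermalization_steps,
                seed=seed + 1,
            )
        if settings.n_steps == 0:
            traj = sim.run(0, seed=seed)
            traj.thermalized = settings.thermalization_steps > 0
            trajectories.append(traj)
            continue
        traj = sim.run(settings.n_steps, seed=seed)
        tau = None
        try:
            tau = autocorrelation_time(traj.rg)
        except ValueError:
            pass
        if auto_length and tau is not None:
            target = int(tau_multiplier * tau) * settings.report_every
            extra = min(
                max(0, target - settings.n_steps),
                (max_production_steps or target) - settings.n_steps,
            )
            if extra > 0:
                more = sim.run(extra - extra % settings.report_every, seed=seed + 2)
                traj = _concat_trajectories(traj, more)
        if tau is None:
            warnings.warn(
                f"replica {rep}: Rg autocorrelation time not estimable; "
                "production length not validated",
                stacklevel=2,
            )
            traj.converged = False
        traj.tau_ac = tau
        traj.thermalized = settings.thermalization_steps > 0
        trajectories.append(traj)
    return trajectories


def _concat_trajectories(a: Trajectory, b: Trajectory) -> Trajectory:
    return replace(
        a,
        steps=np.concatenate([a.steps, a.steps[-1] + b.steps[1:]]),
        frames=np.concatenate([a.frames, b.frames[1:]]),
        rg=np.concatenate([a.rg, b.rg[1:]]),
        energies=np.concatenate([a.energies, b.energies[1:]]),
    )


def autocorrelation_time(series: np.ndarray) -> float:
    """Integrated autocorrelation time of a series, in sampling intervals.

    Computes the normalized autocorrelation by FFT and integrates it up to
    its first zero crossing: ``tau = 1 + 2 * sum(rho_k)``.  White noise gives
    ~1; an AR(1) process with coefficient a gives ~(1 + a) / (1 - a).
    """
    x = np.asarray(series, float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D series of at least 8 points")
    x = x - x.mean()
    var = np.dot(x, x) / x.size
    if var <= 0 or not np.isfinite(var):
        raise ValueError("degenerate (constant) series: tau undefined")
    m = 1 << (2 * x.size - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: x.size] / x.size
    rho = acov / acov[0]
    crossings = np.nonzero(rho[1:] <= 0)[0]
    stop = crossings[0] + 1 if crossings.size else rho.size
    return float(1.0 + 2.0 * rho[1:stop].sum())


#: physical step length at water viscosity for the default dt, seconds.
#: Fixed by Stokes drag (6 pi eta r, bead radius 5 nm) through the reduced
#: friction/time-step calibration.
WATER_SECONDS_PER_STEP = 5e-6
_DT_REF = 1e-3


def physical_time_per_step(viscosity_rel_water: float, dt: float = _DT_REF) -> float:
    """Physical seconds represented by one integration step.

    Linear in solvent viscosity (Stokes drag of a 5 nm-radius bead): water
    gives ~5 us per step; the ~15,000x viscosity inside chromosome
    territories gives ~75 ms.
    """
    if viscosity_rel_water <= 0:
        raise ValueError("viscosity must be > 0")
    return WATER_SECONDS_PER_STEP * viscosity_rel_water * (dt / _DT_REF)
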
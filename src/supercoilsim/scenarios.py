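"""Declarative scenario runner for the four study designs.

Scenarios:

* ``loop_divergent``  — one ~50 kb divergently-transcribed domain closed into
  a loop, convergent motors flanking a swivel at the closure (writhe rises
  in magnitude and saturates by motor stalling),
* ``linear_domains``  — a linear fragment of ~10 divergent-transcription
  domains with full borders (motors, swivels, passage zones); contact maps
  show TAD-like triangles whose borders coincide with motor convergence,
* ``homeostasis``     — same machinery, analysed for abrupt +-2 writhe jumps
  (intersegmental passages) and the recovery that follows,
* ``cohesin_barrier`` — passive fibre with rigid threaded rings and none of
  the transcription machinery: depletion lines but no self-interacting
  domains,
* ``torque_sweep``    — the linear system at motor torques 0/1/2/4 pN nm.

Defaults are desk-scale (replica counts and production lengths far below the
study's ~20M-configuration sampling); every run writes its resolved
configuration and a manifest so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .contacts import (
    bin_map,
    boundary_coincidence,
    contact_map,
    depletion_lines,
    domain_contact_scores,
    write_dense_matrix,
)
from .dynamics import IntegratorSettings, Simulation, Trajectory, autocorrelation_time
from .forcefield import ForceFieldParams
from .io import write_events_tsv, write_topology_tsv, write_xyz
from .model import (
    FiberSystem,
    build_cohesin_system,
    build_linear_system,
    build_loop_system,
)
from .topology import compute_topology_series, TopologySeries

SCENARIO_NAMES = (
    "loop_divergent",
    "linear_domains",
    "homeostasis",
    "cohesin_barrier",
    "torque_sweep",
)

#: default motor torque, pN nm (the majority of the study's simulations)
DEFAULT_TORQUE_PN_NM = 2.0


@dataclass
class ScenarioConfig:
    """Fully declarative description of one experiment."""

    scenario: str
    builder: dict = field(default_factory=dict)
    forcefield: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)
    n_replicas: int = 5
    seed: int = 0
    out_dir: str | None = None
    torques_pn_nm: tuple = (0.0, 1.0, 2.0, 4.0)  # torque_sweep only
    contact_cutoff: float = 1.5
    bin_beads: int = 25

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIO_NAMES}"
            )

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        """Load from YAML (or INI-style ``key: value``) rejecting unknown keys."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        """All defaults materialized (written next to outputs for provenance)."""
        d = dataclasses.asdict(self)
        d["forcefield_resolved"] = ForceFieldParams(**self.forcefield).to_dict()
        d["integrator_resolved"] = dataclasses.asdict(
            IntegratorSettings(**{**self._integrator_defaults(), **self.integrator})
        )
        d["version"] = _version
        return d

    def _integrator_defaults(self) -> dict:
        big = self.scenario in ("linear_domains", "homeostasis", "cohesin_barrier",
                                "torque_sweep")
        return {
            "dt": 0.004,
            "n_steps": 150_000 if big else 400_000,
            "report_every": 2_000 if big else 4_000,
            "thermalization_steps": 20_000,
            "n_replicas": self.n_replicas,
            "seed": self.seed,
        }

    def settings(self) -> IntegratorSettings:
        return IntegratorSettings(**{**self._integrator_defaults(), **self.integrator})

    def params(self) -> ForceFieldParams:
        return ForceFieldParams(**self.forcefield)


def build_scenario_system(
    config: ScenarioConfig, replica_seed: int, torque: float | None = None
) -> FiberSystem:
    """Construct the FiberSystem for one replica of a scenario."""
    b = dict(config.builder)
    torque = DEFAULT_TORQUE_PN_NM if torque is None else torque
    torque = b.pop("torque_pn_nm", torque)
    if config.scenario == "loop_divergent":
        return build_loop_system(b.pop("domain_kb", 50.0), torque)
    if config.scenario in ("linear_domains", "homeostasis", "torque_sweep"):
        return build_linear_system(
            domain_sizes_kb=b.pop("domain_sizes_kb", None),
            torque_pn_nm=torque,
            seed=replica_seed,
            n_domains=b.pop("n_domains", 10),
            terminal_borders=b.pop("terminal_borders", True),
            zones=b.pop("zones", True),
        )
    if config.scenario == "cohesin_barrier":
        return build_cohesin_system(
            n_beads=b.pop("n_beads", 1250),
            spacing_kb=b.pop("spacing_kb", 50.0),
        )
    raise AssertionError(config.scenario)


@dataclass
class ReplicaResult:
    trajectory: Trajectory
    topology: TopologySeries
    system: FiberSystem


@dataclass
class ScenarioResult:
    """In-memory bundle of one scenario run (one entry per condition)."""

    config: ScenarioConfig
    replicas: dict  # condition label -> list[ReplicaResult]
    contact_maps: dict  # condition label -> ContactMatrix (bead resolution)
    out_dir: Path | None


def run_scenario(
    config: ScenarioConfig,
    write_outputs: bool = True,
    write_frames: bool = False,
) -> ScenarioResult:
    """Build, simulate and analyse all replicas (and torque conditions).

    Writes per-replica topology/event logs, bead- and 10 kb-binned contact
    maps, domain scores, the resolved config and a run manifest into
    ``config.out_dir``.  On a stage failure, partial outputs are kept and the
    manifest records the failure.
    """
    out = Path(config.out_dir) if (config.out_dir and write_outputs) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config_resolved.yaml").write_text(
            yaml.safe_dump(config.resolved(), sort_keys=False)
        )
    conditions = (
        [(f"torque_{t:g}", t) for t in config.torques_pn_nm]
        if config.scenario == "torque_sweep"
        else [("run", None)]
    )
    settings = config.settings()
    params = config.params()
    replicas: dict = {}
    maps: dict = {}
    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "version": _version,
        "status": "running",
        "conditions": {},
    }
    try:
        for label, torque in conditions:
            reps = []
            all_frames = []
            for rep, seed in enumerate(settings.replica_seeds()):
                system = build_scenario_system(config, seed, torque)
                sim = Simulation(system, params, settings)
                if settings.thermalization_steps:
                    sim.run(
                        settings.thermalization_steps,
                        report_every=settings.thermalization_steps,
                        seed=seed + 1,
                    )
                traj = sim.run(settings.n_steps, seed=seed)
                traj.thermalized = settings.thermalization_steps > 0
                try:
                    traj.tau_ac = autocorrelation_time(traj.rg)
                except ValueError:
                    traj.converged = False
                topo = compute_topology_series(traj, system)
                reps.append(ReplicaResult(trajectory=traj, topology=topo, system=system))
                all_frames.append(traj.bead_frames())
                if out:
                    tag = f"{label}_rep{rep}"
                    write_topology_tsv(topo, out / f"topology_{tag}.tsv")
                    write_events_tsv(topo.events, out / f"events_{tag}.tsv")
                    if write_frames:
                        write_xyz(traj, out / f"trajectory_{tag}.xyz")
            cmap = contact_map(
                np.concatenate(all_frames), config.contact_cutoff, box=reps[0].trajectory.box
            )
            replicas[label] = reps
            maps[label] = cmap
            if out:
                write_dense_matrix(cmap, out / f"contacts_bead_{label}.txt")
                write_dense_matrix(
                    bin_map(cmap, config.bin_beads), out / f"contacts_binned_{label}.txt"
                )
            manifest["conditions"][label] = {
                "n_replicas": len(reps),
                "n_beads": reps[0].system.n_beads,
                "replica_seeds": [r.trajectory.seed for r in reps],
            }
        manifest["status"] = "completed"
    except Exception as exc:  # keep partial outputs, record failure
        manifest["status"] = f"failed: {exc!r}"
        if out:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    result = ScenarioResult(
        config=config, replicas=replicas, contact_maps=maps, out_dir=out
    )
    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        summarize_run(result).to_csv(out / "summary.csv", index=False)
    return result


def summarize_run(result: ScenarioResult) -> pd.DataFrame:
    """One row per condition x replica x domain: steady-state writhe, events,
    intra/inter contact ratio.

    The steady window is the last half of production; the standard error uses
    an effective sample size from the series autocorrelation time.
    """
    rows = []
    for label, reps in result.replicas.items():
        cmap = result.contact_maps[label]
        for rep, r in enumerate(reps):
            layout = r.system.layout
            scores = (
                {
                    s.domain: s.ratio
                    for s in domain_contact_scores(cmap, layout)
                }
                if layout and layout.domains
                else {}
            )
            wr = r.topology.writhe_domains
            n_dom = wr.shape[1] if wr.size else 0
            if n_dom == 0:
                rows.append(
                    {
                        "condition": label,
                        "replica": rep,
                        "domain": -1,
                        "wr_mean": np.nan,
                        "wr_se": np.nan,
                        "n_passages": 0,
                        "intra_inter_ratio": np.nan,
                    }
                )
                continue
            h = wr.shape[0] // 2
            for d in range(n_dom):
                series = wr[h:, d]
                try:
                    tau = max(1.0, autocorrelation_time(series))
                except ValueError:
                    tau = 1.0
                n_eff = max(1.0, len(series) / tau)
                rows.append(
                    {
                        "condition": label,
                        "replica": rep,
                        "domain": d,
                        "wr_mean": float(series.mean()),
                        "wr_se": float(series.std(ddof=1) / np.sqrt(n_eff))
                        if len(series) > 1
                        else np.nan,
                        "n_passages": sum(
                            1 for e in r.topology.events if e.domain == d
                        ),
                        "intra_inter_ratio": scores.get(d, np.nan),
                    }
                )
    return pd.DataFrame(rows)


def analyze_bundle(out_dir) -> pd.DataFrame:
    """Re-read a written bundle's summary table."""
    path = Path(out_dir) / "summary.csv"
    if not path.exists():
        raise FileNotFoundError(f"no summary.csv under {out_dir}")
    return pd.read_csv(path)
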
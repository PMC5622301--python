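"""Trajectory and series export: XYZ, tab-separated series, HDF5."""

from __future__ import annotations

from .dynamics import Trajectory
from .topology import TopologySeries

__all__ = [
    "write_xyz",
    "write_topology_tsv",
    "write_events_tsv",
    "save_trajectory_h5",
    "load_trajectory_h5",
]


def write_xyz(traj: Trajectory, path, element: str = "C", side_element: str = "H") -> None:
    """One XYZ record per frame: beads then side sites, comment = step index."""
    n = traj.n_beads
    n_sites = traj.frames.shape[1]
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n_sites}\nstep={traj.steps[f]}\n")
            for i in range(n_sites):
                el = element if (i < n or i >= 2 * n) else side_element
                x, y, z = traj.frames[f, i]
                fh.write(f"{el} {x:.5f} {y:.5f} {z:.5f}\n")


def write_topology_tsv(series: TopologySeries, path) -> None:
    """Tab-separated per-frame series: step, Rg, Tw, Wr_total, Wr_domain_1..N."""
    nd = series.writhe_domains.shape[1]
    with open(path, "w") as fh:
        cols = ["step", "rg_nm", "twist", "wr_total"] + [
            f"wr_domain_{d + 1}" for d in range(nd)
        ]
        fh.write("\t".join(cols) + "\n")
        for f in range(len(series.steps)):
            row = [
                f"{series.steps[f]:d}",
                f"{series.rg_nm[f]:.4f}",
                f"{series.twist[f]:.5f}",
                f"{series.writhe_total[f]:.5f}",
            ] + [f"{series.writhe_domains[f, d]:.5f}" for d in range(nd)]
            fh.write("\t".join(row) + "\n")


def write_events_tsv(events, path) -> None:
    """Passage-event log: step, domain, delta-writhe."""
    with open(path, "w") as fh:
        fh.write("step\tdomain\tdelta_wr\n")
        for e in events:
            fh.write(f"{e.step}\t{e.domain}\t{e.delta_wr:.4f}\n")


def save_trajectory_h5(traj: Trajectory, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=traj.frames, compression="gzip")
        h5.create_dataset("steps", data=traj.steps)
        h5.create_dataset("rg", data=traj.rg)
        h5.create_dataset("energies", data=traj.energies)
        h5.attrs.update(
            {
                "n_beads": traj.n_beads,
                "closed": traj.closed,
                "box": traj.box,
                "dt": traj.dt,
                "seed": traj.seed,
            }
        )


def load_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        return Trajectory(
            steps=h5["steps"][:],
            frames=h5["frames"][:],
            rg=h5["rg"][:],
            energies=h5["energies"][:],
            n_beads=int(h5.attrs["n_beads"]),
            closed=bool(h5.attrs["closed"]),
            box=float(h5.attrs["box"]),
            dt=float(h5.attrs["dt"]),
            seed=int(h5.attrs["seed"]),
        )
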
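"""Metropolis pivot sampling of the passive backbone ensemble.

For a motor-free fibre the material frame integrates out of the backbone
marginal (the side sites' orientation space does not depend on the backbone
configuration), so backbone observables — tangent correlations, persistence
length, radius of gyration — can be sampled exactly with pivot Monte Carlo
over the bond + bending + excluded-volume energy.  Pivot moves decorrelate
global conformation in O(n) moves, which makes this the estimator of choice
for equilibrium chain statistics; it also serves as an independent oracle
for the Langevin integrator's Boltzmann sampling.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceFieldParams
from .model import wlc_chain

__all__ = ["backbone_energy", "pivot_backbone_samples"]


def backbone_energy(pos: np.ndarray, params: ForceFieldParams) -> float:
    """Bond + Kratky-Porod bending + repulsive-LJ energy of a backbone path."""
    b = np.diff(pos, axis=0)
    bl = np.linalg.norm(b, axis=1)
    e = 0.5 * params.k_bond * ((bl - params.r0_bond) ** 2).sum()
    t = b / bl[:, None]
    e += params.eps_bend * (1.0 - (t[:-1] * t[1:]).sum(axis=1)).sum()
    n = pos.shape[0]
    d = pos[:, None, :] - pos[None, :, :]
    r2 = (d**2).sum(-1)[np.triu_indices(n, k=2)]
    close = r2 < params.r_cut**2
    if close.any():
        sr6 = 1.0 / r2[close] ** 3
        sr6c = 1.0 / params.r_cut**6
        shift = 4.0 * (sr6c**2 - sr6c)
        e += params.eps_rep * (4.0 * (sr6**2 - sr6) - shift).sum()
    return float(e)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * k @ k


def pivot_backbone_samples(
    n_beads: int,
    n_moves: int = 40_000,
    seed: int = 0,
    params: ForceFieldParams | None = None,
    sample_every: int = 40,
    burn_in_fraction: float = 0.25,
    move_sigma: float = 0.6,
) -> np.ndarray:
    """Equilibrium backbone configurations, shape (n_samples, n_beads, 3).

    Starts from an exact Boltzmann draw of the ideal bending potential and
    applies random pivot rotations accepted by Metropolis on the full
    backbone energy (bonds, bending, excluded volume).
    """
    params = params or ForceFieldParams()
    rng = np.random.default_rng(seed)
    pos, _ = wlc_chain(n_beads, rng, eps_bend=params.eps_bend)
    e = backbone_energy(pos, params)
    burn_in = int(burn_in_fraction * n_moves)
    samples = []
    for m in range(n_moves):
        i = int(rng.integers(1, n_beads - 1))
        rot = _rotation(rng.standard_normal(3), rng.normal(0.0, move_sigma))
        new = pos.copy()
        new[i:] = (new[i:] - new[i]) @ rot.T + new[i]
        e_new = backbone_energy(new, params)
        if np.log(rng.random() + 1e-300) < e - e_new:
            pos, e = new, e_new
        if m >= burn_in and m % sample_every == 0:
            samples.append(pos.copy())
    return np.array(samples)
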
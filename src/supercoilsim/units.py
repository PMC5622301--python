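"""Reduced-unit conventions and genomic/physical conversions.

The simulation works in Lennard-Jones-style reduced units:

* length   sigma   = one bead diameter = 10 nm of 10 nm chromatin fibre,
* energy   eps0    = 1 k_B T (~4.1 pN nm at ~298 K),
* friction gamma   = 1 per bead, bead mass = 1 (defines the time unit).

At the fibre's linear density of ~400 bp / 10 nm, one bead carries 400 bp.
"""

from __future__ import annotations

#: bead diameter in nanometres (the reduced length unit sigma)
SIGMA_NM = 10.0

#: base pairs represented by one bead
BP_PER_BEAD = 400

#: thermal energy in pN nm at ~298 K; converts motor torques to eps0/rad
KT_PN_NM = 4.1


def bp_to_beads(genomic_length_bp: float) -> int:
    """Convert a genomic length in bp to a bead count (400 bp per bead).

    >>> bp_to_beads(50_000)
    125
    """
    if genomic_length_bp < 0:
        raise ValueError(f"genomic length must be >= 0, got {genomic_length_bp}")
    return int(round(genomic_length_bp / BP_PER_BEAD))


def beads_to_bp(n_beads: int) -> int:
    """Exact inverse scale: beads to bp."""
    return int(n_beads) * BP_PER_BEAD


def torque_to_reduced(torque_pn_nm: float) -> float:
    """Motor torque in pN nm -> generalized force in eps0 per radian."""
    return torque_pn_nm / KT_PN_NM
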
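# Model and methods

`supercoilsim` simulates 10 nm chromatin fibre as a twistable bead–spring
polymer and asks whether transcription-generated torsional stress, relaxed
locally by topoisomerase-like elements, is sufficient to fold the fibre into
TAD-like self-interacting domains — and whether passive cohesin rings are
not.

## The fibre model

One bead represents 400 bp of 10 nm fibre (linear density ~400 bp / 10 nm);
the bead diameter sets the length unit sigma = 10 nm, thermal energy sets
eps0 = 1 k_BT, and bead mass and friction set the reduced time unit. All
defaults live in `ForceFieldParams` and print via `supercoilsim params`.

| term | form | default | why |
|---|---|---|---|
| excluded volume | cut-shifted repulsive LJ, r_cut = 1 sigma | eps = 1 eps0 | fibre self-avoidance; the shift vanishes identically at this cutoff |
| backbone bonds | harmonic, rest 1 sigma | k = 800 eps0/sigma^2 | keeps bond fluctuations ~3.5% while allowing dt ~ 4e-3 |
| bending | Kratky–Porod eps_b (1 − cos θ) | eps_b = 5 eps0 | persistence length ~50 nm (measured 50.3 nm by pivot-MC with excluded volume; ideal-chain value 44.8 nm) |
| torsion | 0.5 k φ², φ the side-site ladder dihedral wrapped to (−π, π] | k = 4 eps0/rad² | measured effective twist rigidity 4.01 eps0/rad² |
| swivels | k = 0 on annotated bonds | — | TOP1-like free rotation ahead of each polymerase |
| passage zones | pair prefactor replaced by `zone_epsilon` for any pair touching a zone bead | barrier ≈ 2 eps0 at r = 0.5 sigma | TOP2-like thermally-driven strand passage; the main free parameter for passage rates |
| motors | constant axial torque on the gene-body bead of the motor bond | τ/4.1 eps0/rad per pN nm | see below |
| cohesin rings | 16 tangent 10 nm beads, rigid; harmonic centre-to-anchor restraint | k_anchor = 50 | ~51 nm ring threaded on the fibre |

**Material frame.** Twist needs a frame. Each bead carries a phantom side
site offset 0.5 sigma, tethered by a stiff spring (k = 8000) and kept
perpendicular to the *central-difference* tangent by a harmonic-cosine term
(k_perp = 100). Penalising perpendicularity against both adjacent bonds
separately — the more obvious construction — makes bending anisotropic
(bends in the side-site plane cost extra, inflating the apparent persistence
length by a factor ~5); the central-tangent form leaves bending isotropic,
which we verified against the exact Kratky–Porod angle distribution.
The torsion potential acts on the ladder dihedral (side_i, bead_i, bead_i+1,
side_i+1), well-defined even on straight chains.

**Motors.** A transcribing polymerase rotates its template about the fibre
axis; the reaction torque is taken up by the polymerase and the crowded
nucleoplasm, not by the downstream fibre. The motor is therefore an
*external* torque: a pure force couple between a motor bead and its side
site whose component about the motor-bond axis is exactly τ (in eps0/rad,
converted at k_BT = 4.1 pN nm), signed so the gene-body side winds negative.
A generalized torque on the motor bond's own dihedral — an internal torque
dipole — cannot accumulate supercoiling: both ends of the dipole live in the
same elastic segment, so it only strains that one bond (we verified this
both by torque-balance statics and by simulation). With the external couple,
the domain twist grows until the elastic back-torque matches τ and the motor
stalls, which is the mechanism that saturates the writhe.

**Integration.** BAOAB-splitting Langevin dynamics (unit mass and friction,
kT = 1) for chain sites; rigid cohesin rings move by overdamped Brownian
rigid-body updates (net force/torque about the centre, isotropic mobilities
from the summed bead friction). Default dt = 1e-3; production runs use
4–5e-3, validated by energy conservation (gamma = 0), bond-variance,
equipartition and Rg cross-checks against an independent Metropolis pivot
sampler. A neighbour list (skin 0.5 sigma, rebuilt every 10 steps) handles
excluded volume under minimum-image periodic boundaries; coordinates are
integrated unwrapped so topology measures stay continuous. A step moving any
site more than 0.5 sigma aborts the run with a diagnostic.

**Initial states.** Closed systems start as flat circles (torsionally
relaxed, or with an imposed linking difference wound uniformly into the
frame). Linear systems start from an equilibrium worm-like-chain sample with
a parallel-transported (twist-free) frame — sampling bond angles from the
exact Boltzmann distribution of the bending potential skips the slow global
collapse of a straight rod. Cohesin systems start straight so ring threading
is unambiguous.

**Time scale.** One reduced friction unit corresponds to the Stokes drag of
a 5 nm-radius bead, so one default step is ~5 microseconds in water and
~75 ms at the ~15,000x viscosity of chromosome territories; the conversion
is linear in viscosity.

## Topology measures

* **Writhe**: pairwise solid-angle (Klenin–Langowski) Gauss sum over
  non-adjacent segment pairs; open chains use the open sum without
  artificial closure. Per-domain writhe restricts both segments to the
  domain's bead range (flanking motor beads included by default; toggle
  available). Validated to 1e-3 against a fine independent quadrature of the
  Gauss double integral and exactly antisymmetric under mirror reflection.
* **Twist**: the dihedral sum (the coordinate the torsion potential acts on)
  is the default; for linking numbers we use the exact polygonal-ribbon
  twist in the parallel-transport convention, for which Lk = Tw + Wr holds
  identically (conserved to <1e-4 turns over millions of steps, versus
  ~0.1–0.5 turn apparent drift of the raw dihedral sum from its O(bend²)
  discretisation error).
* **Persistence length**: weighted log-linear fit of tangent–tangent
  correlations over separations up to 150 nm (weights ∝ corr, the
  delta-method weighting for log-transformed decay data), pooled over
  replicas so single-trajectory slow-mode bias averages out. The headline
  measurement samples the backbone ensemble by pivot Metropolis Monte Carlo
  (`supercoilsim.montecarlo`) — exact equilibrium with no initial-state
  bias; Langevin estimates agree but converge much more slowly because the
  excluded-volume swelling of the correlation tail develops on the global
  relaxation time.
* **Passage events**: jumps |ΔWr| ≥ 1.5 between consecutive reports —
  halfway between the thermal writhe fluctuation scale (≲1) and the ±2 of a
  strand passage.

## Contact maps

Contacts are counted per frame for bead pairs within a capture radius
(default 1.5 sigma = 15 nm surface proximity; exposed as configuration) and
block-averaged to 10 kb (25-bead) Hi-C resolution. Domain structure is
scored by the intra/inter contact ratio at matched genomic separations;
boundaries by sliding-diamond insulation minima (window 5 bins, relative
depth ≥ 0.2, and at least 1 count per diamond pixel of flanking signal so
that sparse maps yield no calls); cohesin shielding by the ratio of an
anchor's row band to flanking bands away from the diagonal. The boundary
caller is our addition, validated on synthetic block matrices. Desk-scale
qualitative checks use a 2.5 sigma capture radius, which gives countable
statistics at a few hundred frames where the 15 nm criterion would need
millions of configurations.

## Study scenarios and desk-scale sampling

The four scenarios (`loop_divergent`, `linear_domains` / `homeostasis`,
`cohesin_barrier`, `torque_sweep`) default to the study conditions wherever
stated: 2 pN nm motors, 10 domains sampled from 40–100 kb (the S. pombe
domain-size range; the experimental distribution is not tabulated, so
uniform is our documented approximation), 10-bead passage zones, swivels one
bond ahead of each motor, 16-bead rigid rings at ~50 kb spacing, five
replicas thermalized and run past 8 Rg-autocorrelation times. Production
lengths in this package are desk-scale — single-domain runs of ~10^6 steps
and a few replicas, versus the original ~2x10^7 sampled configurations — and
every reported mean carries the corresponding statistical width.

## What the model reproduces, and known limitations

With the stated parameters the package reproduces: persistence length
~50 nm; stalling motors with writhe that rises and saturates negative;
exact ±2 writhe jumps at intersegmental passages; torque-dependent
intra/inter contact enrichment with boundaries at motor-convergence points;
and depletion lines without self-interacting domains for passive cohesin
rings.

Two quantitative observables fall short of the source values under our
realization: the closed-ribbon twist→writhe partition equilibrates at
~52–58% (rather than ~70%) for ΔLk = −6 on a 100–150 bead ring, bracketed
from both twist-rich and writhe-rich starts; and the steady-state
single-domain writhe at 1/2/4 pN nm reaches roughly 0.6x the source values.
Both discrepancies trace to the same free-energy curve — writhe versus
restoring torque — which here is fixed entirely by the (verified) bending
stiffness, excluded volume and temperature. They would be reconciled by a
somewhat softer effective bending or thinner effective fibre in the original
implementation, or, for the motor-driven numbers alone, by reading the
motor torque as per-bead rather than per-motor; neither reading is
determinable from the stated parameters, so we keep the literal ones and
report our model's honest values. The partition also rises with supercoiling
density, so the ~70% figure may correspond to a higher operating |ΔLk| than
the −6 probed here.

Other limitations: motors are static (no translocation along the fibre);
no nucleosome-scale structure, sequence effects, attractive interactions,
electrostatics or hydrodynamic coupling; absolute passage rates depend on
the qualitative `zone_epsilon` choice and are not calibrated; the
synthetic worm-like-chain initial state and dilute periodic box mean
crowding effects of a full nucleus are absent.
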
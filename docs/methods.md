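# Methods

## Model and procedure

MdMD is biased sampling by selection. A propagator advances the system for
one short sprint; a scalar progress variable is evaluated on the result; the
sprint is kept iff the value strictly exceeds the maximum over the last
`archive_depth` archived values (ties reject, so neutral drift cannot bloat
the archive). On rejection the last archived state is restored and its
velocities are redrawn from a fresh, deterministic substream of the master
seed, so retries differ from the rejected sprint while whole runs remain
bit-reproducible. Because acceptance compares against the archive maximum,
the trace of archived progress values is strictly increasing by
construction; during a sprint the variable is unconstrained and may
transiently pass through otherwise-forbidden values.

The progress variable for map fitting is the cross-correlation
CC = Σρ_aρ_b / √(Σρ_a²·Σρ_b²) — an unnormalized cosine similarity, *not* a
Pearson correlation: the mean is deliberately not subtracted, and a
mean-subtracted variant is available but off by default. For non-negative
maps CC ∈ [0, 1] with CC = 1 iff the maps are proportional
(Cauchy–Schwarz). A model entirely outside the map support scores 0 rather
than raising, so the demon can in principle recover from pathological
starts. The driver is generic over the progress callable; a negative-RMSD
progress variable is provided for testing and for driving toward a known
reference.

## Density synthesis

Each atom contributes g(r) = exp[−3/(2σ²)·‖r−r_n‖²] integrated over voxel
volumes. The kernel separates, so the voxel integral is computed *exactly*
as the product of three 1-D Gaussian-integral (erf) differences — not by
sampling the voxel center — making values independent of grid refinement.
Truncation is per atom, by voxel-center distance within `cutoff_radius`
(default 2σ), a sphere test that is deterministic and makes CC values
reproducible bit-for-bit. The mass lost beyond 2σ is ~1.1% of the
full-space Gaussian integral (verified numerically in the tests).

Conventions, declared once and used everywhere: voxel values are indexed
[i, j, k] along x, y, z; the center of voxel (i,j,k) is
origin + (i+½, j+½, k+½)·spacing; σ = resolution/2 so the 2σ truncation
diameter equals the nominal resolution (if both σ and resolution are
supplied, σ wins); the default synthesis grid is the structure bounding box
padded by the cutoff radius at spacing = resolution/3. Map files are
CCP4/MRC mode 2; on read, axis order is normalized to x-fastest-index, the
MRC2014 ORIGIN header is honored (start indices otherwise), and
experimental maps are not thresholded. Grids must match exactly for CC;
`resample` (trilinear, zero outside the source, clipped at 0) brings one
map onto the other's geometry.

## Propagators

*Elastic network + Langevin.* Springs connect all site pairs within 10 Å of
the reference geometry with a uniform constant (default 1 kcal/(mol·Å²),
E = ½k(d−d₀)²); integration is BAOAB at 2 fs, 300 K, friction 1 ps⁻¹.
With friction and temperature zero the scheme reduces to velocity Verlet;
energy drift over 10 ps is < 0.1% in the tests. Units are Å, ps, amu,
kcal/mol (1 kcal/mol = 418.4 amu·Å²/ps²).

*Hinge Monte-Carlo.* Proposes rigid bends of a declared arm about the hinge
axis, with Gaussian step width `step_scale·√duration` (default
2.0°/√ps) — the diffusive scaling keeps the demon's adaptive sprint length
meaningful for a proposer with no intrinsic clock. Twist proposals about
the arm axis are available but default to zero amplitude.

*External command adapter.* Any engine that reads a PDB and writes an
advanced PDB can serve as the propagator; no specific MD code is bundled
and the adapter asserts the atom count is preserved.

*Restraints.* Tethers use E = k·d² per atom — **not** ½k·d² — matching
force constants quoted per hydrogen-bonding atom in kcal/(mol·Å²); the
convention differs between codes, hence the emphasis. The anticodon helper
tethers the N/O base atoms of residues 34–36 at their current positions
with k ∈ [1, 10] by convention (validated only as k > 0).

*Center-of-mass correction.* Removes net linear momentum and the rigid
rotation implied by the net angular momentum about the COM (pseudo-inverse
of the inertia tensor, so collinear degenerate geometries do not fail);
runs after accepted sprints by default, cadence configurable. Velocities
are re-thermalized only after rejections, not after accepted sprints.

## Demon schedule

Sprint bounds default to [0.05, 5] ps with growth ×1.5 on acceptance and
shrink ×0.5 on rejection, clamped at the bounds; fixed multiplicative
factors are used rather than factors scaled by the progress increment
(simpler, and adequate on every problem exercised here). `archive_depth`
defaults to 3. Termination: goal reached, iteration budget exhausted, or
`max_consecutive_rejections` in a row (status `stalled`). A propagator or
progress failure aborts with the partial result and status `error`.

## Geometry analyses

The interarm angle is the angle between the dominant principal axes of the
acceptor-stem and anticodon-stem P-atom clouds, each axis oriented from the
stem end nearest the hinge residues outward — a true bend angle with no
axis-sign ambiguity, invariant under rigid motion and atom reordering.
Stem windows are configuration with canonical defaults (acceptor 1–7 and
66–72, anticodon 27–31 and 39–43, hinge 26/44/45) and must be overridden
for structures with non-canonical numbering; published per-structure angle
tables depend on the chosen windows, so exact reproduction of any
particular table is not promised.

Contacts: "base atoms" are all heavy non-sugar, non-phosphate nucleotide
atoms (a reproducible convention; atom-level definitions vary in the
literature). A tRNA residue contacts a protein partner residue when any
partner Cα is within the cutoff (default 4 Å) of any of its base atoms,
and an RNA partner when any partner base atom is. The tRNA side uses base
atoms in both modes, for symmetry with the base-to-base rule. Occupancy
denominators count all frames, including frames with no contacts.

RMSF superposes frames onto the first frame and then onto their mean
(via the alignment selection) before measuring per-residue fluctuations of
the P (or Cα) marker atom. Convergence of a trajectory toward a reference
is declared at RMSD < 3 Å (threshold configurable). Docking superposes
each frame's anchor selection (default residues 34–36) onto the reference
anchor by least squares; superposition everywhere excludes reflections
(det = +1) to preserve nucleic-acid chirality, pairs atoms by
(chain, resid, name) falling back to (resid, name), and requires ≥ 3
non-collinear pairs.

## Synthetic generator

The pseudo-tRNA is two helical arms of P pseudo-atoms (rise 2.8 Å/residue,
twist 32.7°/residue) meeting at the requested hinge angle, with two base
pseudo-atoms per residue placed inward toward the arm axis, numbered 1–76
so all default windows resolve (acceptor arm: residues 1–16 and 60–76;
anticodon arm: 17–59 with a 7-residue loop arc at the tip). Two choices
matter:

- **Height-matched, phase-opposed strands.** Paired stem residues sit at
  identical heights along the arm axis with a phase offset of π. This makes
  each stem's P cloud symmetric about the arm axis, so its principal axis
  *is* the arm axis and the generator's requested hinge angle and the
  measured interarm angle agree to well under a degree across 60–120°.
- **Backbone radius 4 Å.** The stems are only 5–7 residues long; at the
  full A-form P radial distance (~9 Å) the radial variance of such a short
  helix's P cloud exceeds its axial variance and the principal-axis
  direction becomes ill-conditioned. The narrowed radius keeps the axial
  direction dominant. Nothing downstream depends on the radius except
  through the density maps themselves.

`deform_hinge` rotates the anticodon arm rigidly about the normal to the
two stem axes through the hinge-P centroid; the pivot and axis are fixed
points of the rotation, so deformations compose additively in the bend
angle and invert exactly. Target maps add seeded Gaussian voxel noise
(a stated fraction of the clean maximum) clipped at 0.

What the generator does *not* emulate: chemistry and sterics, base-pair
hydrogen bonding, sequence effects, ions, solvent, internal stem
deformations (arms move rigidly), and experimental map artifacts beyond
i.i.d. voxel noise (no CTF, no local-resolution variation, no masking).
Passing recovery tests therefore demonstrate the correctness of the
selection algorithm, the density model and the geometry pipeline — not
fitting accuracy on real micrographs.

## Problem sizes and numerics

The recovery experiment (the package's end-to-end benchmark) uses the
76-residue, 228-atom pseudo-tRNA, an 8 Å target map at 2.67 Å spacing
(grid ≈ 40×50×25 covering both endpoints of the motion), demon goal
CC = 0.98 within 400 iterations — a deliberate desk-scale configuration
that completes in well under a second per run, with ten seeds used
wherever a success rate is quoted. The companion rigid-displacement check
for the elastic-network engine uses a ~1.4 Å whole-molecule shift (initial
CC ≈ 0.96): small enough that the engine's friction-limited center-of-mass
diffusion closes the gap within 200 iterations, large enough that the
starting model does not already satisfy the goal. The quadrature cross-check compares the
erf-exact voxel integrals against a midpoint rule at 10× finer resolution;
the superposition cross-check against a five-stage nested rotation-grid
search converging to ~1e-5 Å. Degenerate inputs fail loudly: all-zero maps
make CC undefined, collinear selections refuse to superpose, hinge
deformation refuses collinear stem axes, and negative RMSD or temperature
are rejected.

## Known limitations

All-atom force-field MD (explicit solvent, PME, SHAKE) is out of scope;
the built-in engines are coarse stand-ins and the external-command adapter
is the route to production MD codes. Single connected model per map
(no simultaneous multi-chain fitting); no Fourier-space synthesis,
B-factor weighting, sharpening, or local-resolution masking; mmCIF is not
written. CC as implemented is the plain cosine form; if a mean-subtracted
(Pearson-style) coefficient is needed for comparison with other software,
enable it explicitly and expect different absolute values.
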
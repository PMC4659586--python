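# Methods

`ptmetad` implements the enhanced-sampling analysis chain used to map
conformational free-energy landscapes of protein kinases — well-tempered
metadynamics over a small set of collective variables (CVs), parallel
tempering, free-energy reconstruction, enthalpy/entropy decomposition, and
sub-microsecond flexibility analysis — on analytic model systems whose basin
free energies are known exactly by quadrature.  This note documents the
models, the estimators, the numerical choices, and what the synthetic
systems do and do not emulate.

## Units and conventions

Energies are kJ/mol internally with k_B = 0.0083144621 kJ/mol/K; lengths in
Angstrom, times in ps, angles in radians (degrees at the CLI).  Reported
basin free-energy differences and thermodynamic fits are in kcal/mol
(1 kcal = 4.184 kJ).  Raw interchange files (HILLS, COLVAR) carry kJ/mol and
ps.  Atom indices are 0-based in the library; path-CV milestones are
1-based, so the progress variable s spans [1, P].

## Model systems and their oracles

Every generated potential carries a `ground_truth` record with basin
definitions and a quadrature oracle, so each downstream estimator is tested
against an exact answer rather than against another sampler.

* **Tilted quartic double well** `U(x) = h (x^2-1)^2 + (dE/2) x`.  The
  separatrix is the middle root of U'; basin dF per temperature comes from
  adaptive quadrature of the Boltzmann weight on each side.  This is the
  minimal stand-in for a two-state conformational flip.
* **Entropy pair**: two locally harmonic basins with curvatures k and
  k*width_ratio joined by a soft-min of scale 1 kJ/mol, minima offset by
  delta_e.  In the harmonic limit dH = delta_e and
  dS = -(k_B/2) ln(width_ratio) exactly, which makes the toy a clean target
  for the dG(T) regression.  A narrow Gaussian bump at the crossing adjusts
  the barrier to `barrier_height`; the default barrier (20 kJ/mol) equals
  the natural soft-min crossing height of the default parabolas, so the bump
  amplitude is ~0 and the exact quadrature dF(T) line reproduces the
  harmonic dH to 0.04 kJ/mol.  Requesting barriers far from the natural
  crossing makes the bump large and the basins less harmonic; the quadrature
  oracle remains exact either way.
* **Dihedral flip chain**: per dihedral
  `u_i = (1 - cos(t - in_i))(1 - cos(t - out_i))`, which vanishes with zero
  gradient at both reference conformations, so "in" and "out" are exact
  stationary states by construction.  Pairwise couplings `c u_i u_j` and an
  asymmetry term (exact for antipodal references) preserve this property.
  Ground truth for up to three dihedrals is a dense periodic Riemann grid;
  basins are defined by the dihedral-similarity value at threshold n/2.
* **Two-channel binding topology**: a 2D plane with a deep Gaussian well at
  the origin (crystallographic pose), a shallower well on the channel axis
  (external pose), a circular ridge with one or two Gaussian notches (exit
  channels of prescribed saddle heights) and a confining quartic wall.
  Wells are kept narrow relative to the ridge radius so that the channel
  saddle heights match the requested barriers to < 0.1 kJ/mol; a
  min-over-angle / max-over-radius grid search verifies this.
* **Fluctuation trajectories**: pseudo-protein Cartesian frames with
  independent isotropic Gaussian displacements (expected RMSF =
  sqrt(3) sigma) plus sinusoidally driven collective modes (variance
  amplitude^2/2 over whole cycles).  The mean structure is a helical
  CA-like chain (rise 1.5 A, radius 2.3 A, 100 deg per residue): a straight
  chain would make rotational superposition degenerate about the chain axis,
  which is both unphysical and numerically ill-conditioned.  Planted modes
  are by default orthogonalised against the six rigid-body fields of the
  mean structure so that superposition-based PCA can recover them exactly.

## Sampling

Underdamped Langevin dynamics with the BAOAB splitting (friction 1 1/ps,
timestep 0.01 ps, unit mass by default).  BAOAB was chosen for its
configurational accuracy at large timesteps; the timestep is a toy-scale
choice, an order of magnitude below the stability limit of the stiffest
default potential.  Potential energies recorded at saved frames are the
same floating-point evaluations used for the forces, so energy bookkeeping
is exact by construction.

Parallel tempering attempts swaps of adjacent replicas on the standard
alternating even/odd schedule.  The acceptance log-ratio is

    (b_i - b_j)(U_i - U_j) + b_i [V_i(s_i) - V_i(s_j)] + b_j [V_j(s_j) - V_j(s_i)]

with per-replica metadynamics biases V evaluated exactly (direct summation)
at both partners' CV positions; on acceptance coordinates are swapped and
velocities rescaled by sqrt(T_new/T_old).  Randomness is organised as
counter-based substreams of one master seed (replica k's stream depends only
on (seed, k); exchange decisions draw from a separate stream), so ensembles
are bit-reproducible and replica 0 of an n-replica run is identical to a
single-replica run at the same seed when no swap is accepted.

## Well-tempered metadynamics

Hills of initial height w0 are deposited every `deposition_stride` steps at
the current CV values, scaled by `exp(-V/(k_B dT))` with
dT = (gamma - 1) T.  Defaults (w0 = 2 kJ/mol, stride 2000, gamma = 5,
widths 0.1 in similarity units / 0.3 A for distances) follow common practice
for kinase-style conformational metadynamics; the toy examples in the tests
use smaller strides so runs converge within seconds.

During dynamics the bias force is looked up in a grid cache (each deposition
adds its separable Gaussian to value and gradient grids; multilinear
interpolation in between).  Deposited heights, logged bias energies and
exchange terms always use exact direct summation over the hill list, so the
entire bias is exactly reproducible from the HILLS file alone; the grid
affects only the integration path, not any reported energy.  Hills are
stored as deposited (well-tempered-scaled heights), the common HILLS-file
convention.

The well-tempered ensemble (WTE) is plain metadynamics on the potential
energy as a CV — no bespoke code path.  The energy bias is grown during a
preliminary phase (default: the first 20% of the run) with CV hills
withheld, then frozen while the CV bias runs; reweighting accepts the frozen
energy bias as an extra per-frame log-weight.  The growth length and the
energy-CV hill parameters are configuration knobs.

## Free-energy reconstruction

Two deliberately independent estimators:

1. **Bias integration**: F(s) = -(gamma/(gamma-1)) V(s, t_end), min-shifted
   to zero.
2. **Time-independent reweighting**: frame weights
   w(t) = exp(beta [V(s(t), t) - c(t)]) with the offset
   c(t) = (1/beta) ln [ Int exp(g beta V) ds / Int exp(beta V/(gamma-1)) ds ],
   g = gamma/(gamma-1), evaluated on the reconstruction grid by log-sum-exp
   with trapezoidal end weights.  The weighted histogram on any target CV
   grid gives F = -k_B T ln p; the target CVs need not be the biased ones,
   which is how surfaces are reprojected onto path variables.

Unsampled histogram nodes carry +inf and are excluded from basin sums,
never imputed.  Basin dG = -k_B T ln(Z_a/Z_b) sums Boltzmann weights of
sampled nodes inside rectangular basin windows (the constant cell volume
cancels); toy basins come from the potential's ground truth, user data
requires explicit windows.  Free energies are gauge-fixed by min-shifting,
so any constant offset of the bias leaves every dG unchanged.

Convergence is monitored by recomputing dG at fixed time intervals from
both estimators; a run is declared converged when the last three
checkpoints of each series stay within 0.3 kcal/mol and the estimators
agree within 0.3 kcal/mol at the end.  A basin-visit counter (entries into
each basin window along the CV series) guards against the degenerate case
of a flat-looking but one-sided run.  Replica-level dG values used for the
dG(T) fit are means of the bias-integration series over the last half of
the checkpoints — time-averaging suppresses the residual oscillation of
the converged well-tempered bias — with the checkpoint spread as the
uncertainty.

## Enthalpy/entropy decomposition

dG(T) is assumed linear over the replica ladder (constant heat capacity):
ordinary least squares of dG on T gives dH as the intercept and dS as minus
the slope, with TdS reported at 305 K, the production temperature, by
default.  The points are the replica temperatures themselves, not
interpolated ones.  Curvature is not modelled; instead `range_robustness`
refits on temperature subranges (full range, drop-hottest, drop-coldest by
default) and flags the estimate unstable when dH moves by more than twice
the largest fit standard error.  Note the long extrapolation from the
305-400 K window to the T = 0 intercept: per-replica dG noise is amplified
about five-fold in dH, which is why the per-replica time-averaged estimator
matters.

## Flexibility analysis

Windowed RMSF: the trajectory (after discarding an equilibration segment)
is cut into non-overlapping windows; within each window frames are
superposed on the window mean (iterative Kabsch alignment, initialised
covariantly on the first frame and gauge-fixed each pass, run to
convergence — typically two or three passes) and the per-atom RMS deviation
from the window mean is averaged over windows.  Trailing partial windows
are dropped.  Window alignment suppresses slow drifts by construction;
alignment also absorbs ~6/(3N) of isotropic variance, negligible for the
atom counts used.

PCA diagonalises the covariance of the aligned selected coordinates (SVD of
the centred data matrix).  Cross-trajectory projection superposes each
frame on the reference mean structure (an explicit atom map is required
when selections differ) and dots with the leading eigenvectors; the
explored area is summarised by the convex-hull area over the first two
components, an explicit scalar substitute for visual diffusion comparisons.
For quasi-degenerate mean structures the rigid-rotation modes are only
partially suppressed by alignment; the helical mean geometry of the
generator avoids this regime.

## Problem sizes

The test suite and the demo run at desk scale by design: 1D metadynamics
runs of 0.8-3 million steps (8-30 ns of toy time), five-replica ladders at
305-400 K with 1.5 million steps per replica, 2D runs of 1.5 million steps,
and fluctuation trajectories of 2,000-20,000 frames.  At these sizes the
two estimators agree to ~0.01 kcal/mol and recover quadrature basin dF to
0.1-0.3 kJ/mol on the 1D toys; these sizes are choices of the package's
test design, and all of them are parameters, not constants.

## Known limitations

* Bias grids (and therefore biased CV sets) are limited to one or two CVs;
  the CV *definitions* support any number (the similarity CV takes any
  dihedral count).
* No multiple-walker or transition-tempered variants; no adaptive hill
  widths.
* No funnel restraints or standard-state corrections for the binding toy;
  its dG is a basin ratio on the 2D plane, not a binding constant.
* The synthetic systems emulate the statistical structure of conformational
  landscapes (metastability, entropy/enthalpy splits, exchange overlap,
  planted flexibility modes) but none of the chemistry: no solvent, no
  force field, no real protein geometry.  Passing tests demonstrate the
  correctness of the estimators and machinery, not the accuracy of any
  particular kinase free-energy surface.
* dG(T) linearity is an assumption; strongly curved dG(T) is only detected
  (range-robustness flag), not modelled.
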
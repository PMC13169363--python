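# Methods

## The problem

In a periodic cell the bulk polarization **P** is multivalued: it is
defined only modulo the *quantum of polarization* **Q**, whose columns are
the lattice vectors times the elementary charge (`core.quantum_matrix`).
The reduced polarization **p** = **Q**⁻¹**P**, wrapped componentwise into
[−1/2, 1/2), is the natural circular variable.  Two consequences shape the
whole package: (i) raw polarization datasets jump discontinuously between
*branches* separated by integers in reduced coordinates, which poisons any
smooth regression; (ii) errors must be measured circularly, with the von
Mises error

    vME = 1 − (1/3N) Σᵢ Σ_α cos[2π (p_pred,iα − p_calc,iα)]  ∈ [0, 2],

which is invariant under branch changes.

The package provides the two routes to a learnable polarization —
data-driven branch unwrapping, and Wannier-center displacement learning —
plus the downstream analyses they enable: IR spectra from the dipole
autocorrelation and the hydration-shell decomposition of the spectrum and
of hydrogen-bond statistics in water–ethanol mixtures.

## Conventions

* **P** is the total cell dipole in e·Å (not a dipole density); `e = 1`
  internally, with Debye conversion (1 e·Å = 4.803205 D) applied at I/O.
* Wrapping is half-open: `p = x − floor(x + 1/2)`, so a value at exactly
  +1/2 maps to −1/2.  This makes reduction deterministic.
* Coordinates are Cartesian Å, atoms 0-indexed; cells are stored
  row-major on disk (lattice vectors as rows) and used column-major in the
  quantum matrix.
* Per-frame cells are supported throughout (the quantum is recomputed per
  frame); the bundled fixtures all use one fixed cubic cell.

## Covariant regression

Targets are 3-vectors, so kernels must satisfy K(R·a, b) = R K(a, b).  We
use the standard symmetry-adapted construction at λ = 1: each atomic
environment is expanded in Gaussian radial functions × spherical
harmonics; the l = 1 channel, written in Cartesian form
V[s, n] = Σⱼ gₙ(r_ij) f_cut(r_ij) r̂_ij, supplies covariant vector
features, and the power spectrum of the full expansion (all l ≤ l_max,
per species pair) supplies rotation-invariant scalar features.  The
kernel between environments of the same central species is

    K(a, b) = k₀(a, b)^(ζ−1) · V_aᵀ V_b   (3×3),

with k₀ the normalized scalar-feature dot product; cross-species kernels
are zero.  Equivariance is exact by construction — the acceptance checks
measure it at machine precision, not at a fitted tolerance.

Defaults (all exposed): cutoff 4.0 Å, 6 radial functions, l_max = 4,
Gaussian width 0.3 Å, ζ = 2 (integer ζ keeps the kernel positive
semidefinite), regularization 10⁻⁸ relative to the mean kernel diagonal.
The global polarization model uses the summed-environment kernel, so each
prediction decomposes exactly into atom-centered dipole contributions —
the decomposition the shell-resolved spectra consume.  The Wannier model
is one sub-model per chemical species with per-atom targets.  No
sparsification is implemented: kernels are dense, which is appropriate at
the desk scale this package targets (tens to hundreds of frames, tens of
atoms).  Training solves the 3M×3M block system by Cholesky
factorization; a singular system with vanishing regularization raises an
explicit error rather than returning a least-squares compromise.

## Data-driven unwrapping

The preprocessing loop (module `unwrap`) needs no auxiliary charge model
and no Born-charge derivatives:

1. train a probe model on a random ~5% of the data;
2. predict the remainder; apply the Hartigan dip test per component to
   the signed residuals.  Residual modes separated by integers
   (multimodal) mean branches are resolvable; a broad unimodal cloud
   means the probe subset itself mixed branches, and a new subset is
   drawn (up to `max_restarts`, default 20);
3. residual components below 0.5 mark points already on the main branch;
4. remaining points are shifted by the nearest integer of the signed
   residual.  (Truncation of, e.g., a residual of 0.98 would leave the
   point off-branch; off-branch residuals cluster near integers, so
   rounding is the reading that actually moves every point onto the main
   branch.)

Numerical choices that matter in practice:

* **Probe regularization ladder.**  Each subset is diagnosed at
  regularizations 10⁻³, 1, and 100 (relative), and the multimodal
  diagnosis with the most integer-concentrated residuals is kept.  A
  lightly regularized probe resolves branches when its subset sits on one
  branch; when the branch scatter is independent of the configuration a
  flexible 10-point fit leaks the scatter into its predictions and washes
  the modes out, while a heavily shrunk probe (it need not be accurate)
  exposes them.
* **Circular re-centering.**  Residuals are shifted by their circular
  mean before rounding, so a probe fit level near a half-integer cannot
  split one residual mode across a rounding boundary.
* **Leave-probe-out assignment.**  A near-interpolating probe has ~zero
  in-sample residuals, which would silently leave its own points on their
  original branches; the probe points are therefore assigned with a
  second model trained on the already-unwrapped remainder.
* **Refinement.**  The main-branch points are then used to train a model
  that re-wraps *all* points, iterated to a fixed point (at most 4
  rounds).  On the standard fixture this lifts offset recovery from ~96%
  to 100%.
* The dip verdict threshold is p < 0.05 in any component
  (any-component rule), bootstrap n = 1000 against the uniform null,
  seeded.  Data are declared *verified single-branch* when every probe
  residual is below 0.5 in magnitude, whatever the verdict.

### The dip statistic

`diptest` is implemented in-package.  The statistic is computed from its
definition — the smallest uniform-norm distance from the empirical CDF to
any unimodal CDF — by scanning candidate modes at the data points (the
jump at the mode is absorbed by the mode) and solving each one-sided
convex/concave band-fitting problem exactly with convex hulls.  The
implementation neglects one coupling: the convex fit left of the mode and
the concave fit right of it must also join monotonically.  Dropping that
constraint makes the statistic a provable lower bound on Hartigan's dip;
cross-validation against a linear-programming feasibility oracle on small
random samples shows exact agreement in all but rare configurations,
where the deviation stays below ~0.003.  Because the bootstrap null uses
the same statistic as the sample, the p-value remains an exact Monte
Carlo test.  Canonical values hold exactly: two equal point masses give
dip = 1/4, n distinct near-uniform points give 1/(2n), and the statistic
is bounded by [0, 1/4].

## Wannier centers

Each center is doubly occupied; with valence charges Z (defaults O:6,
C:4, H:1 — pseudopotential, not nuclear, charges) the cell dipole is
P = e Σ Zᵢ Rᵢ − 2e Σ rⱼ.  Assignment to atoms is pure bookkeeping: the
regrouped form P = e Σᵢ [(Zᵢ − 2Nᵢ) Rᵢ − Δᵢ], with Δᵢ = Σⱼ 2δ_ij the
displacement sum, is an algebraic identity for *any* ownership.  (The
prefactor must be Zᵢ − 2Nᵢ: each center carries two electrons; a
single-count prefactor does not reproduce the direct sum.)  Because
displacements are stored minimum-image, an ownership across a periodic
boundary shifts the regrouped P by an integer number of quanta; the
identity is therefore checked on the reduced polarization, and exactly
when no image wrap is active.

Assignment is nearest-atom (ties within 10⁻⁹ Å raise).  Atoms are
labeled by the species within `label_cutoff` = 1.8 Å — wide enough for
covalent bonds, too short for hydrogen-bond partners — and the modal
center count per label is tabulated (ties break to the larger count, with
a warning).  Miscounted atoms are repaired by transferring, between
bonded surplus/deficit pairs, the surplus atom's center closest to the
deficit atom; the procedure conserves the total count exactly, is
idempotent, and raises when no bonded transfer can resolve the counts
(single transfers only — a center two bonds away from where it belongs is
reported, not chased).  Bonds come from the input or from a covalent-radius
criterion (1.2 × the radius sum).

## IR spectra

I(ω) ∝ ω² ∫⟨P(t)·P(0)⟩ e^{iωt} dt, computed as: mean removal, biased FFT
autocorrelation summed over the three components, truncation at T/2, Hann
apodization, cosine transform with 2× zero padding, multiplication by the
squared wavenumber.  The proportionality constant is 1 — spectra are in
arbitrary units; positions and shapes are the contract.  No quantum
correction factor is applied (classical trajectories in, classical
spectra out).  Slightly negative off-peak values from apodization are at
numerical noise level and are not clipped, so the decomposition closure
I = I₁ + I₂ + I_c stays exact: I_c is computed as I − I₁ − I₂, which is
algebraically identical to the symmetrized cross-correlation route
(verified independently in the tests).  Peak positions are the windowed
argmax refined by a 3-point quadratic fit; a flat or curvature-free
window raises rather than returning a fabricated peak.

## Hydration structure

Hydrogen bonds use the Luzar–Chandler geometric criterion by default
(O···O ≤ 3.5 Å and H–O_d···O_a angle ≤ 30°, both configurable); a bond
is counted once, and a water's participation counts it as donor or
acceptor.  The ideal-mixing baseline interpolates the mean count linearly
in the ethanol mole fraction between two endpoint compositions, so the
excess Δn_HB vanishes at the endpoints by construction.  The distance of
a water to ethanol is measured from its oxygen to the nearest β-carbon
(the methyl carbon, not bonded to oxygen); the first-shell cutoff
defaults to the first minimum of the β-C–O(water) radial distribution
function of the analyzed trajectory, with a fixed override supported.
The excess H-bond density profile divides the per-bin excess
participation by the spherical-shell volume and reports never-populated
bins as missing values, not zeros.

## The synthetic generators

The `synthetic` module produces every input with known ground truth:
rigid idealized water (0.96 Å, 104.5°) and ethanol molecules placed by
rejection sampling (heavy-atom separation ≥ 2.2 Å, bounded attempts)
with uniform random rotations; Wannier centers at bond/lone-pair
construction sites (bond and lone-pair radii deliberately differ, 0.45 vs
0.25 Å on oxygen, so displacement sums carry an orientation-dependent
signal instead of cancelling by symmetry); a smooth point-charge +
damped-bond-dipole polarization oracle (charge values fixed but
arbitrary — only smoothness, neutrality and determinism matter); and
harmonic dipole trajectories with known line positions.  Branch-scattered
data are built by reducing the oracle polarization and *then* adding a
uniform random integer 3-vector in [−2, 2]³ per point — reducing after an
integer shift would be a no-op, so scattering must follow reduction for
the offsets to be a recoverable ground truth.  Recovery is scored up to
the global integer gauge, which unwrapping cannot (and need not) fix.

Every generator is a pure function of its seed.  What the fixtures do
*not* emulate: liquid structure (no equilibration — molecules are placed,
not thermalized), intramolecular flexibility, realistic charge
distributions, or long MD correlation.  Passing tests therefore
demonstrate the correctness of the algorithms and their contracts
(equivariance, conservation, closure, recovery), not the physical
accuracy of any trained model on real trajectories.

## Problem sizes

The standard fixtures use 4-molecule boxes (9–12 Å), datasets of 50–200
frames, 2¹⁴-step dipole trajectories, and 100–500-fixture ensembles for
the identity and repair checks — sizes chosen so the full pipeline runs
in about a minute while every contract is still exercised end to end.

## Known limitations

* Unwrapping assumes few accessible branches; systems with free charges
  that hop branches with small barriers may never yield a single-branch
  probe subset, and the loop then fails explicitly after `max_restarts`.
* The Wannier repair only moves centers across one bond.
* No uncertainty estimates, no kernel sparsification, no GPU path.
* The dip statistic's junction approximation (above) can underestimate
  the dip by ~10⁻³ in rare configurations; verdicts are unaffected in
  all tested scenarios.
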
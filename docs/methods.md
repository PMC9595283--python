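# Methods

`aortamech` characterizes the region-dependent mechanical behavior of
arterial tissue from uniaxial tensile data.  This note records the models,
the virtual-biaxial estimation procedure, the synthetic study conditions,
and the numerical and design choices a maintainer would want to know.

## Kinematics and stress

All specimens are flat strips loaded uniaxially along either the
circumferential or the longitudinal tissue axis.  The deformation is
incompressible with symmetric lateral contraction,

    F = diag(λ, λ^{-1/2}, λ^{-1/2})        (material frame: circ, long, radial)

with the loaded axis carrying λ.  The Cauchy stress follows from a strain
energy W(C) via `T = −pI + 2F (∂W/∂C) Fᵀ`, with the Lagrange multiplier p
fixed by a traction-free lateral face.  Stress is reported in MPa; this is
a convention of the file format, not a claim about any particular data
source — the constitutive literature frequently omits units, so the column
name (`stress_MPa`) carries it explicitly.

### The two elimination conventions, and why there are two oracles

For an *anisotropic* material the two lateral faces of the strip carry
different extra stresses, so under the constrained symmetric-lateral
kinematics one cannot make both traction-free at once.  Two conventions are
in circulation:

1. **Radial-face elimination** — set the radial extra stress to zero:
   `T = σ₁₁ᵉ − σ₃₃ᵉ`.  This is what the package's closed forms implement
   (for the Fung model the multiplier term visibly involves only the radial
   strain coefficients b3, b5, b6; for the Holzapfel model p = c/λ because
   the fibers have no radial component).
2. **Path derivative** — `T = λ·dŴ/dλ` along the uniaxial path, which
   equals `σ₁₁ᵉ − (σ₂₂ᵉ + σ₃₃ᵉ)/2`, i.e. it splits the multiplier across
   both lateral faces.

The two coincide exactly when the lateral extra stresses are equal: for the
Fung model on the subspace b2=b3 ∧ b4=b5 (circumferential loading; b1=b3 ∧
b4=b6 for longitudinal), for the Holzapfel model only when the fibers lie
on the loading axis, and *always* for the CMM energy-consistent form
(whose in-plane transverse and radial terms are constructed jointly from
the stored energies).  Both conventions are implemented as independent
numeric oracles:

* `lagrange_elimination_oracle` — central differences of W with respect to
  the principal components of C, pushed through the tensor formula with p
  from the radial face.  It reproduces the hand-derived closed forms to
  better than 1e−6 relative error for arbitrary parameters, validating the
  multiplier-elimination algebra.
* `numeric_stress_oracle` — central difference of Ŵ(λ), second-order in
  the step size, with an optional step-halving truncation check.  It
  validates the closed forms on the lateral-symmetric subspace and the CMM
  energy-consistent form everywhere.

The off-subspace discrepancy between the conventions is real (order 1–10%
of the stress for typical parameters) and is asserted as nonzero in the
test suite so that the distinction is never silently lost.

## Constitutive models

**Fung orthotropic exponential** (7 parameters): `W = c1/2 [exp(Q) − 1]`,
Q a quadratic form in the principal Green–Lagrange strains with
coefficients b1..b6 (index 1 = circumferential, 2 = longitudinal,
3 = radial).  Swapping b1↔b2 and b5↔b6 exchanges the circumferential and
longitudinal stress responses; this symmetry is a test invariant.

**Holzapfel two-fiber-family** (4 parameters): neo-Hookean matrix
`c/2 (I1 − 3)` plus two identical exponential fiber families
`k1/(2k2) [exp(k2 (I4 − 1)²) − 1]`.  In the implemented closed forms
cos²γ pairs with the circumferential stretch, so algebraically γ is the
fiber angle from the *circumferential* axis; the source literature
sometimes words the convention differently, and the equations — not the
wording — are normative here.  No tension-only switch is applied to the
fibers: the closed forms are implemented literally, and the fitted stretch
windows start at λ = 1 so fiber compression is rare and mild.  `I4 − 1` is
computed in difference form `(λ²−1)cos²γ + (λ⁻¹−1)sin²γ` so the stress is
exactly zero at λ = 1 in floating point.

**Constrained mixture (CMM)** (9 parameters): an incompressible elastin
network pre-stretched in-plane by G1 (circ) and G2 (long) — its radial
pre-stretch follows from constituent incompressibility as 1/(G1·G2) — and
two collagen fiber-family groups (c2_k, c3_k) sharing the deposition
pre-stretch Gh and symmetric angle ±α.  The elastin energy is normalized
to vanish in the elastin natural configuration (a constant offset with no
effect on stress); the tissue still carries residual stress at λ = 1
whenever the pre-stretches are non-unit, which is physiological.
Constituent mass densities are absorbed into the stress-like moduli.  The
default stress form (`energy_consistent`) is the analytic λ·dŴ/dλ of the
stored energies; a `literal` form preserving an ambiguous printed grouping
of the fiber term (an apparently duplicated λ² factor) is kept behind a
flag so the discrepancy between the two readings is measurable rather than
silently resolved.

Overflow guard: all exponent arguments are checked against 700; exceeding
it raises a `NonFiniteStressError` naming the stretch — never silent
saturation.

## Two-regime slope analysis

Arterial stress–stretch curves are J-shaped: a compliant elastin-dominated
regime followed by a steep collagen-recruited regime.  Curves are first
truncated at fiber breakage, detected as the earlier of (a) the global
stress maximum and (b) the first sliding window (7 points) whose
least-squares tangent falls below half its running maximum; the detection
rule is this package's own, as only the concept of truncation is standard.
Each regime's tangent is then taken from an R²-optimal linear window: the
low-stiffness window is anchored at the curve's first point, the
high-stiffness window at its last point, and the free endpoint is scanned
exhaustively over all windows of ≥ 5 points (OLS stability under noise).
R² ties are broken toward the longer window (lower-variance slope).  The
derivative of the fitting equation is evaluated at the window midpoint —
the window's own OLS slope by default, with a local-quadratic option for
sensitivity checks.  The transition stretch is the midpoint between the
two windows' inner ends.  A ≥ 5-point overlap of the two optimal windows
flags a single-regime (degenerate) curve; slopes are still returned.

Both slopes scale exactly linearly with a rescaling of the stress axis,
and the high slope exceeds the low slope on every curve generated from the
three models with active fiber terms — both are test invariants.

## Virtual biaxial datasets

A region's circumferential and longitudinal specimens are cross-mapped
exhaustively (every C specimen paired with every L specimen of the same
region).  With the study's specimen counts — PAC/PAL 35/29, PPC/PPL 25/25,
DAC/DAL 26/28, DPC/DPL 28/28 — this yields 1,015 + 625 + 728 + 784 = 3,152
virtual pairs, hence 9,456 fit cases across the three models.  The pairing
is deterministic (circumferential-major) and a seeded without-replacement
subsampling mode exists purely for runtime control; it is never a default.
Cross-region pairing and resampling with replacement are out of scope.

## Parameter estimation

Per-direction fits minimize the unweighted squared stress residual with
`scipy.optimize.least_squares` (TRF, bounds, `x_scale='jac'`), multistart
from 8 seeded Latin-hypercube points over the bounds (log-spaced for
parameters spanning more than three decades).  Default bounds:
stress-like parameters [1e−6, 10] MPa, exponential shape parameters
[1e−4, 50], angles [0, π/2] rad, pre-stretches [0.8, 2.0] — generous
headroom around values reported for thoracic aorta.  Multistart stops
early once a start is exact to ~1e−7 of the data norm.  A fit is
*converged* when its R² reaches the configured floor (0.9 by default);
the optimizer's internal status is deliberately not used, since it reports
failure when the evaluation budget halts at an already-excellent solution.

**Plausible intervals and common-range integration.**  For each direction
a per-parameter plausible interval is computed by a re-optimizing residual
profile: the parameter is fixed at grid values marching outward from the
optimum (warm-started, with a retry from the global optimum when marching
strands on a secondary ridge) while the remaining parameters are refitted;
the interval is the contiguous region where the residual norm stays within
a factor (default 1.05) of max(minimum, 1e−4 × data norm) — the floor
keeps the threshold meaningful on noiseless data.  Interval boundaries are
interpolated between grid points, and near-optimal multistart solutions
further widen the interval along correlated ridges (a fixed-others 1-D
profile was tried and rejected: it slices across the strong c–k1–γ ridges
and produced empty intersections for virtually every pair).  The two
directions' intervals are intersected per parameter to a *common range*;
if any intersection is empty or thinner than 1e−3 of the parameter span,
the residual factor relaxes along the non-decreasing schedule
{1.05, 1.1, 1.25, 1.5} (never tightens — a test invariant).  A narrow but
non-empty range at the cap is padded to minimum width and used; an empty
range falls back to an unconstrained joint fit with a warning.  The joint
fit refits a single vector on the concatenated two-direction residual
(both directions equally weighted), starting from both direction optima,
their average, and Latin-hypercube points; if the constrained joint fit is
materially worse than the two direction fits jointly imply is attainable
(beyond the schedule cap), the unconstrained refit is used and flagged.

**What is recoverable.**  The Holzapfel model's four parameters are
identifiable from a noiseless virtual pair and are recovered to within 5%
(usually machine precision) under multistart.  The Fung and CMM parameter
vectors are *not* identifiable from uniaxial data — their strong
inter-correlations are themselves one of the analysis outputs — so the
estimation contract for those models is reproduction of the stress–stretch
curves (RMSE below 1e−3 of the peak stress on noiseless pairs), not
parameter identity.

Distribution summaries report min / 1Q / median / 3Q / max per parameter
and region over converged fits (linear-interpolation quartiles);
non-converged fits are excluded and counted.

## Statistical pipeline

Every sample passes a Shapiro–Wilk gate (normal iff p ≥ 0.05; constant
samples are errors).  Samples failing the gate are Box–Cox transformed
with the maximum-likelihood λ before any mean comparison; for two-group
comparisons a single λ is fitted on the pooled sample (shifted positive if
needed) so both groups receive the same transform.  Regional differences
are tested two ways, both emitted and labeled: pairwise t-tests over the
six region contrasts (PA–DA, PP–DP, PA–PP, DA–DP, PA–DP, PP–DA) and
one-way ANOVA with Bonferroni-corrected post-hoc pairwise tests
(statsmodels).  The t-test is Welch's by default — the group variances
differ regionally — with a pooled-variance switch.  An audit log records
every gate decision and transform so the no-untransformed-test-on-
non-normal-data rule is checkable.

Correlations (Spearman by default, average ranks for ties; Pearson
optional) are computed per region for every variable pair; a pair is
*reported* only when significantly correlated in all four regions, the
four coefficients are averaged into `mean_r`, and sign uniformity across
regions is flagged.  The Fung anisotropy ratio b1/b2 is included as a
derived variable in the correlation stage.  The pipeline is validated on
synthetic nulls and alternatives (type-I error within [2%, 10%] at nominal
5%; power ≥ 90% for a 1-SD shift at n = 50; reported-in-all-four-regions
rate ≤ 1% for independent pairs), not against any particular experimental
coefficient — those depend on data this package does not ship.

## Synthetic study conditions

The generator emulates a porcine descending-thoracic-aorta uniaxial
campaign.  Defaults, chosen once:

* **Specimen counts** per region and direction: PAC/PAL 35/29, PPC/PPL
  25/25, DAC/DAL 26/28, DPC/DPL 28/28 — the published design.
* **Generating model**: Holzapfel (identifiable, so recovery is testable
  end to end); Fung and CMM generators exist with their own region ranges.
* **Stretch grids**: 80 points from 1 to 1.5 (circumferential) or 1.65
  (longitudinal) — circumferential specimens transition earlier.
* **Region-level parameters**: uniform draws from per-region plausible
  ranges centred on magnitudes reported for thoracic aorta (c ≈ 0.05 MPa,
  k1 ≈ 0.1 MPa, k2 up to ≈ 3.6 in the stiffest region).  The
  distal-posterior (DP) ranges sit highest so DP is the stiffest region in
  both regimes and directions, and fiber angles stay below π/4 so
  circumferential specimens are stiffer than longitudinal ones — the two
  qualitative orderings the cohort must exhibit.  CMM ranges additionally
  keep the collagen exponential physiological over the stretch window
  (peak stresses of a few MPa): with a deposition pre-stretch around
  1.1–1.25 the fibers are already taut at reference, so c3 stays ≲ 1.5.
* **Heterogeneity**: per-specimen lognormal jitter (σ = 0.08) on the
  stress-like moduli, creating realistic parameter spread for the
  distribution summaries.
* **Noise**: multiplicative Gaussian, SD = 2% of the pointwise stress
  (load-cell noise scales with signal), clipped at zero.

Everything derives from the single cohort seed; the ground truth (region
parameters and each specimen's jittered parameters) is stored alongside
every cohort.  What the generator does *not* emulate: image-based stretch
measurement, stress computation from force and measured thickness, rupture
and post-breakage behavior, within-specimen spatial heterogeneity, and
preconditioning hysteresis.  Passing tests therefore demonstrate that the
*procedure* is correct and calibrated, not that any particular biological
parameter value is right.

## Scale choices

The routine test and acceptance runs use reduced problem sizes chosen to
exercise every code path: the full 9,456-case enumeration is exact and
instantaneous, while bulk fitting is demonstrated on a cohort capped at
5×5 specimens per region (100 pairs, one model) and recovery on 20
noiseless pairs.  Fitting all 9,456 cases is a plain loop over the same
machinery (`aortamech fit --model all`) and scales linearly.

## Known limitations

* The radial-face elimination convention is inherited from the printed
  closed forms; a free-lateral-stretch (fully traction-free) solution
  would require relaxing the symmetric-contraction kinematics and is out
  of scope.
* Fung b3, b5, b6 multiply out-of-plane strains that coincide under the
  uniaxial kinematics, so some combinations are structurally
  non-identifiable from uniaxial data; the fitting contract acknowledges
  this (curve recovery, not parameter identity).
* The common range is a per-parameter box; genuinely coupled constraints
  (e.g. c·k1 ridges) are captured only through the profile widening and
  the joint refit, not as joint confidence regions.
* Shear deformation and higher invariants (I5), layered-wall models,
  growth and remodeling dynamics, and compressible formulations are out of
  scope.
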
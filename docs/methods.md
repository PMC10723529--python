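# Methods

This note records the models, parameter choices and numerical decisions
behind each module, what the synthetic generators do and do not
emulate, and the known limitations.

## Scattering models (`sans`)

The three empirical intensity models are

* broad peak (two peaks):
  I(q) = C₀/(1 + (ξ₀|q−q₀|)^m₀) + C₁/(1 + (Ξ₁|q−q₁|)^m₁) + B
* broad peak + correlation length:
  I(q) = C₀/(1 + (ξ₀|q−q₀|)^m₀) + C₁/(1 + (Ξ₁q)^m₁) + B
* correlation length: I(q) = C₀/(1 + (ξ₀q)^m₀) + B

with derived quantities d₀ = 2π/q₀ (the real-space spacing of the
scattering inhomogeneities) and ν = 1/m (polymer scaling exponent).
The absolute-value bars around q−q₀ are required to keep the power real
for non-integer exponents; renderings of such models often leave them
implicit.

Fitting is weighted least squares in linear intensity (curves carry
absolute-scaled intensities and per-point 1σ uncertainties); a
log-space residual mode exists as a diagnostic only.  Initialization is
deterministic: the background starts at the minimum intensity, the
correlation lengths at 2π/(q-range width), the exponents at 2, and the
peak position at the argmax of the intensity-to-running-median ratio
evaluated away from the window-truncated edges.  Five seeded
multiplicative restarts (log-normal, σ = 0.4) guard against local
minima; the lowest-cost converged solution is kept and non-convergence
raises instead of returning defaults.  Parameter uncertainties come
from the Gauss–Newton covariance scaled by the reduced chi-squared.
Fits run over the full stored q-range by default; `qmin`/`qmax` trim it
explicitly, since the measured curves carry no stated trimming rule.

The synthetic p14ARF-detected reference condition uses the published
constraints m₀ = 1/0.66, m₁ = 1/0.35, q₀ = 2π/180 Å⁻¹, ξ₀ = 85 Å,
Ξ₁ = 160 Å on 100 log-spaced points over the instrument range
0.004–0.45 Å⁻¹ with 1 % relative Gaussian noise.  The amplitudes are
not published; C₀ = 1, C₁ = 10, B = 0.01 were fixed once so that the
low-q correlation term dominates the decade below the pseudo-Bragg peak
and the background sits well below both terms at high q, as in the
measured condensate curves.  Both broad-peak variants are provided
because the data could be described either by a second peak (q₁) or by
a correlation-length second term; presentation offsets applied to
published figures are assumed absent from fitting.

## Chain building and conformer pools (`chain`, `conformers`)

Chains are built residue-by-residue with ideal backbone geometry
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°;
ω = 180°) using NeRF placement; only the Cα trace is kept, since every
downstream observable (R_g, pair distances, bead scattering, surrogate
shifts) needs backbone geometry only.  The consecutive Cα–Cα distance
under this geometry is 3.80 Å, satisfying the 3.8 ± 0.1 Å virtual-bond
invariant.

Steric control: two Cα atoms three or more residues apart may not come
within 4.0 Å.  On a clash the builder redraws the dihedrals of a window
of movable residues preceding the clash and rebuilds from the earliest;
the window deepens as retries at the same residue accumulate (80
retries per residue, 50 conformer restarts) so compact dead ends are
escaped.  Directive-structured residues (secondary-structure state
helix/strand with confidence > 5) always keep canonical dihedrals
(−57, −47) / (−140, 135) and are never redrawn.

The coil library is a five-basin Gaussian mixture over (φ, ψ) —
PPII (−75, 145), extended β (−120, 130), α_R (−65, −40), α_L (55, 45)
and a broad bridge basin, weighted 35/35/20/5/5 % — a documented
approximation to database coil sampling.  Non-cooperative sampling
draws both angles from a Gaussian centered at (−112.6, 123) with the
dispersion parameter interpreted as the σ in degrees (the 115–140 range
is accepted); this interpretation is flagged because the original
description does not state units.  Cooperative pools introduce the
stated fraction (0/12.5/25/37.5 %) of conformers whose unstructured
regions are fully β-strand.

R_g is the mass-uniform radius of gyration over Cα positions.  For a
protonated single-component chain this geometric R_g stands in for a
neutron-contrast-aware calculation up to a constant; the scaling factor
ν solves R_g = ρ₀N^ν with ρ₀ = 1.927 Å, the standard empirical
denatured-state prefactor (configurable).

The surrogate shift predictor adds fixed secondary-structure offsets
(helix: Cα +2.6, Cβ −0.4, C′ +1.7, N −1.5, HN −0.25 ppm; strand:
−1.5/+2.2/−1.5/+1.5/+0.35) to embedded random-coil values, classifying
each residue from its local dihedrals.  It reproduces the sign
conventions of secondary shifts, not the accuracy of a trained
predictor; `predict_shifts(external=...)` passes through an externally
computed table unchanged so published predictors can be swapped in.

## Bayesian refinement (`bayes`)

Observables enter through Gaussian likelihoods evaluated at ensemble
averages: chemical shifts with variance ε²_CS + α²_CS (experimental
plus prediction error) and the scaling factor with variance ε²_ν.  The
per-atom prediction-error defaults are Cα 0.4, Cβ 0.5, C′ 0.5, N 1.2,
HN 0.2 ppm (configurable; no published values exist for them).  The
joint likelihood is the product of the scaling term and all shift
terms.

The posterior over the full weight simplex is intractable to grid
directly, so refinement uses cyclic coordinate updates with persistent
per-coordinate priors: each conformer carries a 1D density over its
weight coordinate x ∈ [0, 1], initialized to the conditional of the
uniform simplex distribution, (1−x)^(n−2).  One iteration sweeps all
conformers in seeded shuffled order (the seed affects only visit
order); a visit multiplies the current joint likelihood along the ray
"x for this conformer, the rest scaled by (1−x)" into the prior,
normalizes by the trapezium rule, sets the weight to the posterior mean
and renormalizes the rest proportionally (an O(1) global-scale update).
Because each sweep multiplies one more likelihood factor into every
coordinate's prior, the scheme reproduces the posterior-as-new-prior
sharpening of the original 15,000-iteration protocol: after t sweeps
the effective likelihood is L^t and the ensemble-average scaling factor
converges onto the observation.

The fixed 201-point grid is densified toward both ends by a smoothstep
warp (x = 3u² − 2u³).  A uniform grid cannot resolve the
simplex-conditional prior, whose mass sits at x ≈ 1/n, once n exceeds a
few hundred; the warped grid resolves it for pools beyond 10⁴ while
also resolving weights near 1 for small pools.  Convergence is
monitored through the trajectory of the ensemble-average ν (flagged
when its range over the trailing 100 iterations falls below 10⁻⁴);
degenerate pools whose conformers carry identical observables return
uniform weights with an explicit status.  Top-k selection (default 160)
sorts by weight with ties broken by conformer index.  Refined ensembles
are compared with a two-sided rank-sum test on their final weights —
exact permutation null for small tie-free samples, normal approximation
otherwise — with p ≥ 0.05 declared degenerate (the threshold is a
package default; none is published).

Two properties bound what refinement can do.  The uniform simplex prior
is itself highly informative about the ensemble average (its standard
deviation scales as n^(−1/2)), so with a single broad scaling
observation (ε_ν = 0.296) and a scaled-down iteration budget the
refined average moves only partway from the pool mean toward the
observation; the pool construction therefore matters as much as the
refinement, exactly as in the original protocol where pools were built
spanning the relevant ν range.  And a single scalar observation leaves
the posterior degenerate along the iso-average ridge; weights within
the ridge are determined by the prior, not the data.

## Lattice assembly and scattering (`lattice`)

Assemblies place one conformer per site of a 2D square or rectangular
lattice — sampled with replacement, weight-proportionally when
refinement weights exist — rotated uniformly over SO(3) (quaternion
sampling) and translated so the center of mass sits exactly on the
lattice point.

Orientationally averaged intensities use the Debye sum over Cα beads of
equal scattering length (the contrast-matched single-component
assumption), computed through a pair-distance histogram: per 1 Å bin
the kernel sin(qr)/(qr) is evaluated at the bin's mean distance with a
second-order variance correction, which keeps the transform within
~10⁻⁴ of the exact O(N²) double sum while costing O(N²) distances once
plus O(n_bins·n_q).  This replaces reciprocal-grid Monte-Carlo
integration; the observable is identical.

The grid search enumerates every configuration (default: all array
sizes 2×2–4×4, spacings 160–200 Å in 10 Å steps, both space groups,
square constrained to dX = dY; 270 configurations), computes the
ensemble-average curve over n_rep seeded assemblies (default 8; the
replicate count behind the published average is unstated), interpolates
onto the target grid linearly in log I, fits an amplitude and flat
background analytically by weighted linear least squares, and returns
the argmin chi-squared with the full table.  Ties break
deterministically: smallest site count, then dX, then dY, then space
group order.  Per-configuration, per-replicate seeds derive from a CRC
of the configuration, so a curve generated by `gen_lattice_curve` at a
configuration is reproduced exactly by the search at that
configuration.

Intermolecular distance histograms exclude all intramolecular pairs.
Bins are centered on multiples of the bin width (edges offset by half a
width): with the coarse 50 Å bins used for meso-scale spacings, a
feature commensurate with the bin scale (e.g. the ~200 Å
nearest-neighbor spacing) then falls on a bin center instead of being
split across an edge.  Modes are the centers of local-maximum bins; a
moving-average smoothing window is available but defaults to off, since
coarse binning already smooths.

## FRAP (`frap`)

The pipeline follows the standard correction chain: (I − I_bkgd) /
(I_cell − I_bkgd) for cells or (I − I_bkgd)/(I_ref − I_bkgd) for
droplets; normalization maps the mean of the ten pre-bleach frames to 1
and the first post-bleach frame to 0; the recovery fit is
R(t) = R_post + R_inf·(t/t_½)/(1 + t/t_½) over post-bleach frames with
R_post fixed at the observed first post-bleach value and bounds
t_½ ∈ [frame interval/10, 10 × duration] (all post-bleach frames are
used; no early-frame exclusion rule is published).  Mobility is the
plateau average of the last ten frames over the pre-bleach average —
the fitted amplitude R_inf is reported separately because the two
coincide only for fully converged recoveries.  The effective bleach
radius fits φ(x,y) = F_i·exp(−K·exp(−2r²/r_e²)) to the post/pre image
ratio with center, F_i, K, r_e free, failing when K ≤ 0 (no localizable
bleach); D_app = (r_e² + r_n²)/(8t_½).

D_app is an approximation: on simulated pure-diffusion movies it
recovers the true coefficient to ~20 % (systematically low), monotone
in D across 0.1–5 µm²/s.  The 25 % tolerance used in validation
reflects this known bias, not fitting noise.

## Synthetic data (`synth`)

Every generator is bit-reproducible from (parameters, seed) and can
emit a JSON sidecar (`SimulationSpec`) that regenerates the artifact
exactly.

The FRAP movie simulator evolves a uniform fluorophore field on a
256×256 reflecting grid by exact spectral (cosine-transform)
propagation of the heat equation — unconditionally stable and exact per
frame, in place of explicit time stepping.  The bleach is an
instantaneous Gaussian-profile attenuation exp(−K·exp(−2r²/r_e²))
applied immediately before the bleach frame is recorded; global
exponential photofading, an additive camera offset and Poisson–Gaussian
noise complete the observation model.  The frame interval defaults to
one sixth of the expected half-time so any D in 0.1–5 µm²/s is well
sampled.  Not emulated: diffusion during the bleach pulse, reaction
(binding) contributions, droplet boundary effects (the field fills the
frame; a finite-disk option exists), or detector nonlinearity — so
passing closed-loop tests demonstrates correctness of the analysis
chain for pure diffusion, not robustness to binding-dominated recovery.

Cell images are three-tier disk compositions (background < nucleus <
nucleolus) with Poisson plus Gaussian read noise (σ = 2 counts);
nucleoli are placed at evenly spaced jittered angles so ground-truth
object counts are unambiguous, and the noise seed can be varied
independently of the geometry.  Real nucleoli are neither disk-shaped
nor tier-constant; the fixtures validate threshold nesting, clustering
and counting, not biological segmentation accuracy.

`gen_spanning_pool` builds the refinement study condition: equal
subpools from non-cooperative sampling (dispersion 115°), the coil
library, and partial strand directives (20/40/60 % of residues),
spanning ν ≈ 0.5–0.8 continuously — emulating the systematic variation
of secondary-structure propensity across the original starting pools.

## Imaging (`imaging`)

Segmentation: Gaussian smoothing (σ = 4 for nuclei in cell images,
σ = 0.33 for nucleoli), three-class multi-Otsu; nuclear mask ≥ 0th
threshold, nucleolar mask ≥ 1st threshold (nested by construction);
DBSCAN clustering of mask pixels into objects.  The DBSCAN neighborhood
is 2.5 px with a minimum count of 16: on an integer pixel grid a radius
of 2 contains at most 13 pixels, so a 16-count core is geometrically
impossible at radius 2 — 2.5 px (21 neighbors) is the smallest radius
compatible with that count, which in turn rejects speckle below roughly
4×4 px.  Manual curation is replaced by QC flags (border-touching
objects, 3-MAD area outliers); nothing is removed silently.  Z-scores
normalize per-object channel means over the analyzed object population
(pooling across plates is the caller's choice).  The phase-diagram
"condensed" call uses an IOD threshold supplied by the caller, with 3×
a dilute-field baseline as the suggested default; C_sat per row is the
lowest concentration at or above threshold.

## NMR (`nmr`)

R1/R2 are independent per-residue single-exponential fits (log-linear
initialization, Levenberg–Marquardt refinement); hetNOE is the
saturated/unsaturated intensity ratio.  CPMG dispersion profiles are
fit to three alternatives — flat f(x) = c, fast exchange
R2o + (φ/k_ex)(1 − tanh(k_ex·x)/(k_ex·x)) with φ = p_A·p_B·Δω², and
slow exchange R2o + k_ex·(1 − sin(Δω·x)/(Δω·x)).  The printed source
forms are typographically garbled ("f(x)=R2o+ϕKex1−xKextanhKexx",
"f(x)=R2o+Kex1−sin(Δωx)Δωx"); the implementations are the standard
fast/slow-exchange expressions matching those symbol sets, with the
timing variable x treated as the half-echo-spacing-derived variable in
seconds (its precise definition is not published).  The better
exchange model is accepted over the flat model by an F-test at 95 %
confidence; parameter errors are standard deviations over 200
Monte-Carlo resampled refits started from the fitted solution.

## Known limitations

* The surrogate shift predictor captures sign conventions, not
  predictor-grade accuracy; quantitative shift-restrained refinement of
  real data should inject an external prediction table.
* Geometric Cα R_g ignores solvent-layer and deuteration contrast
  effects; adequate for protonated single-component pools only.
* The coordinate-update refinement shares the simplex prior's
  informativeness about the ensemble average (see above); conclusions
  about how far a broad single observation can move an ensemble carry
  that caveat by design.
* Lattice scattering treats beads as equal point scatterers; form
  factors, excluded volume and 3D space groups are out of scope.
* The FRAP model is pure diffusion; binding/reaction contributions and
  multi-exponential recoveries are not modeled.
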
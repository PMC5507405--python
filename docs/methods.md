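# Methods

This note documents the models, conventions, numerics and limitations of
the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signed network inference

A `FoldChangeRecord` is one gene's response (treated/control ratio and
p-value) to one pathway perturbation. The calling rule is the screen's
own: an edge requires p < α (default 0.05) and ratio ≥ θ or ≤ 1/θ
(default θ = 1.8; both bounds inclusive — fold changes are multiplicative,
so "±1.8-fold" is read as a symmetric ratio criterion). Records from
inhibited conditions imply the opposite regulation sign. If stimulated and
inhibited conditions imply *contradictory* signs for the same
(pathway, gene) pair, no edge is recorded and a warning is emitted;
likewise a species-level cell whose contributing genes disagree collapses
to 0. Dermal/epidermal expression fractions are carried as metadata only.

The shipped default 5×5 matrix is a partial reconstruction from the
regulations that are certain (WNT stimulates the placode suite including
its own inhibitors and FGF; BMP opposes that suite and induces its own
inhibitors; FGF represses the epithelial WNT targets including *Fgf20*;
each dedicated inhibitor suppresses its pathway); entries not pinned down
by those statements are zero. `validate_self_inhibition` checks the
advisory structural claim that each pathway carries a net negative
self-loop, either on the diagonal or through its dedicated-inhibitor
2-cycle.

## Linear stability analysis

`build_model` parameterizes the sign matrix as
`J[i,j] = sign(M[i,j])·magnitude[i,j]` off-diagonal and
`J[i,i] = sign(M[i,i])·magnitude[i,i] − decay[i]`. Defaults are
magnitudes 1, decay 1 h⁻¹; the parameter scan samples magnitudes, decays
and diffusivities log-uniformly over [0.1, 10]. These are deliberately
uncommitted choices: the claim being probed is qualitative (the sign
structure *can* break symmetry), not a fitted kinetic model.

`dispersion` evaluates `λ(k) = max Re eig(J − k² diag(d))` on 256 grid
points over [0, k_max] (default k_max 10) and always refines the peak with
a bounded scalar minimization around the coarse argmax, so an unstable
band narrower than the grid spacing is still detected. The Turing flag is
λ(0) < 0 together with a positive refined peak; band edges come from
linear interpolation of the grid's zero crossings. The eigenvalue with
maximal real part is used directly; a nonzero imaginary part at the peak
is reported as `oscillatory` to distinguish wave instabilities from
stationary bands. The test suite verifies exact agreement with the
two-species closed form (tr J < 0, det J > 0,
d₂J₁₁ + d₁J₂₂ > 2√(d₁d₂ det J)) on 1,000 random systems, choosing k_max
per system from the analytic peak location so the scan covers the band.

## Reaction–diffusion simulation

The nonlinear kinetics preserve the analyzed linearization: for deviations
v = u − u\* about the homogeneous steady state (u\* = 1 by default),
`f_i = Σ_j J_ij φ(v_j)` with `φ(x) = s·tanh(x/s)`. At v = 0 the Jacobian
is exactly J, so the dispersion relation applies verbatim; the saturation
scale s (default 0.5; 0.25 in the shipped exemplar) bounds growth and sets
the pattern amplitude, keeping all concentrations positive in the shipped
scenarios (verified by test). Time stepping is explicit Euler with
flux-form centered diffusion; the diffusive CFL limit dt ≤ h²/(4 d_max) is
checked up front and violations are refused with a suggested dt. Seeded
single-mode experiments initialize along the leading eigenvector of
J − k²diag(d), so the measured early-time growth is a clean exponential; a
mode near the dispersion peak is used for the consistency check because
there λ is flat in k and the discrete Laplacian's wavenumber distortion
(−(4/h²)sin²(kh/2) vs −k²) contributes least.

The two-species exemplar (J = [[1, −2], [3, −4]], d = (1, 40)) has
k* ≈ 0.53 and is the workhorse for dispersion–simulation consistency and
the cut-edge experiment. Emergent wavelengths are compared against 2π/k*
shortly after emergence (t ≈ 24 h at these rates); the saturated pattern
coarsens slowly thereafter, which is physical, not numerical.

## Chemotactic aggregation

The volume-filling Keller–Segel model is discretized conservatively: all
fluxes live on cell faces, and under no-flux boundaries total cell mass is
conserved to rounding error (measured ~1e−16 relative per 1,000 steps).
The advective face flux takes ρ from the upwind cell (positivity) times
the volume-filling factor 1 − ρ/ρ_max of the *receiving* cell, so aggregates
saturate at the packing density instead of overshooting. The advective
CFL number is monitored each step. BMP activity enters as additional
attractant degradation (−bmp·c), which reproduces the erosion direction
without inventing unreported couplings.

The uniform state (ρ̄, c̄ = αρ̄/(δ+bmp)) is linearly unstable iff
χ₀ > D_ρ(δ+bmp)/(α ρ̄ (1−ρ̄/ρ_max)); the closed form is cross-checked in the
tests by bisection on the maximal linear growth rate. Exemplar parameters
(D_ρ = 0.05, D_c = 1, α = δ = 1, ρ_max = 1, ρ̄ = 0.5, χ₀ = 1, i.e. 5×
threshold) give a fastest mode near k ≈ 1.1 and ~10–20 aggregates on the
32×32-unit domain. Erosion experiments start from a settled pattern
(300 h pre-run) so that the bmp = 0 control is stable within 10% over the
assay window; focus areas use a fixed threshold of 0.6 ρ_max so that the
time series are comparable across BMP levels.

## Cut-edge boundary conditions

The cut edge is the left boundary; the along-edge direction is periodic
and the far side closed. For the reaction–diffusion mechanism the
inhibitor species takes a Dirichlet-0 condition *on its deviation* at the
cut — the secreted inhibitor is diluted into the culture medium, clamping
it at its well-mixed level — while the activator is merely truncated
(no-flux). This yields discrete foci hugging the edge. For the
chemotactic mechanism the cell field is truncated (no-flux: cells cannot
leave the tissue) and the secreted attractant takes the absorbing
condition on the cut, because it, too, physically dilutes into the medium.
A fully reflecting cut would act as a mirror — effectively *doubling* the
missing neighbours rather than removing them — and produces
boundary-hugging half-aggregates; the absorbing attractant edge is what
expresses "fewer neighbours with which to nucleate clustering" in a
continuum model, and it produces the observed stand-off. Edge distances
are normalized per seed by the pattern wavelength; for the RD field the
wavelength is estimated on the interior half of the domain with the
edge-normal 1-D trend removed, since the boundary layer otherwise
dominates the radial spectrum, and foci are segmented with a 90th-
percentile threshold to keep edge and interior foci separable.

## Trajectory analysis conventions

Units are micrometres and minutes throughout. A cell acquires condensate
identity iff its final sample lies inside an ROI; entry time is the first
time from which it stays inside until the track end, and samples after
entry are discarded. Windows are 360 min, counted backward from the entry
time (condensate) or final sample (intercondensate); windows not fully
covered by the track, or with fewer than 2 samples, are discarded. The
angle reference is the vector from the window-start position to the future
condensate centre: the entered condensate for condensate tracks, and for
intercondensate tracks the ROI centre nearest the *window-start* position.
The latter choice makes the bias-free null exactly isotropic — the
reference is fixed by information available at the window start, and the
subsequent displacement of an unbiased walk is independent of it.
Zero-net-displacement windows have an undefined angle (flagged, excluded
from angle pools) but keep persistence = 0. Persistence is clamped into
[0, 1] against rounding on collinear paths. KS p-values are asymptotic by
default with an exact small-n option.

A caveat that matters when interpreting recovered "pre-switch" windows:
because a captured cell's condensate necessarily lies near its position at
the attraction switch, the direction to that centre partially embeds the
cell's own earlier displacement, producing a mild toward-bias in windows
*before* the switch — an intrinsic property of this retrospective
construction (it would affect real tracking data analyzed the same way),
not of the generator. At the per-dataset sample sizes used here
(~40–70 condensate windows) this bias sits near the edge of detectability,
which is why the window comparisons are summarized as the median
Bonferroni-corrected p across datasets rather than pooled into one
overpowered test; the uniformity check at bias 0 pools both classes'
windows, which cancels the small survival bias created by removing
captured cells from the intercondensate class.

## Synthetic-data generator

The trajectory generator emulates the tracked-cell data structure: cells
take one step per 20-min frame (the acquisition interval is not dictated
by the data; 20 min is the package default) with Rayleigh step lengths
(scale κσ, σ = 1.5 μm) and uniform headings, on an unbounded plane whose
400×400 μm spawn region contains 4 condensate centres on a jittered grid;
370 cells per dataset, 1,500-min duration. In the final 360 min, cells
within 45 μm of a centre draw headings from a von Mises distribution
aimed at the centre with concentration κ_vM = 10b/(1−b+1e−9) (b = 0 is
exactly uniform; b → 1 ballistic); a cell reaching the 15-μm capture
radius is recorded as entered and tracking halts. Capture is only active
after the switch — condensates do not exist before the pattern forms.
These conditions were chosen once so that a dataset yields ≥ 40 condensate
0–6 h windows (the published figure's order of magnitude, with power to
spare) while keeping pre-switch windows statistically quiet, and are not
tuned per analysis. Chemokinesis multiplies the step scale; note that a
pure scale change multiplies accumulated *and* Euclidean displacement
identically and leaves persistence exactly invariant — so, at generator
truth, an elevated accumulated velocity with strictly unchanged Euclidean
velocity is not simultaneously achievable; the corresponding published
contrast reflects finite-sample behaviour of noisy data.

What the generator does *not* emulate: cell division and death, collective
migration, drift or imaging artifacts, heterogeneous cell speeds, and any
coupling between neighbouring cells. Passing pipeline-recovery tests
therefore demonstrates correctness of the measurement and test chain under
known structure, not biological realism of the walk model.

Fold-change tables draw replicate log fold changes from
Normal(±ln effect, sd) per regulated (pathway, gene) pair and report the
geometric-mean ratio plus a one-sample t-test p-value; decay tables apply
multiplicative lognormal noise (coefficient of variation cv) to exact
exponentials with log-uniform rates, with a constant-plus-noise reference
transcript. Movies render each cell as a bilinearly-deposited impulse
blurred by an isotropic Gaussian PSF, preserving subpixel positions.

## Half-life estimation

The default fit is log-linear regression of ln(rel_expr) on t with the
intercept fixed at 0 (rel_expr(0) ≡ 1 by construction); a free-intercept
variant is available as a robustness check, and a single-time-point
closed form (t½ = −t ln2 / ln rel_expr) covers paired designs. The decay
rate is clamped at ≥ 0 (a non-decaying transcript is flagged stable with
infinite t½); R² is computed on the natural scale; nonpositive points are
dropped with a warning and ≥ 3 usable points including t = 0 are required.
Standard errors account for the error structure induced by normalizing to
a noisy t = 0 anchor — the log-scale errors of the t > 0 points share a
common component, Cov = σ²(I + 11ᵀ) — and, in screen mode, σ² is pooled
across all transcripts (they share the measurement noise level), which
makes ±2 SE intervals well calibrated even from 3 post-block time points.
The candidate filter (t½ ≤ 90 min inclusive, extracellular annotation,
expression above floor) reports per-criterion pass/fail; detection status
is input metadata, not recomputed.

## Velocimetry

Interrogation windows are 32 px with 50% overlap and ±8 px search by
default (16 px windows for the small simulation movies); matching is
normalized cross-correlation with 3-point Gaussian subpixel refinement.
Windows whose contrast falls below 0.2× the frame std are flagged invalid
(their correlation surface is flat and the subpixel fit ill-conditioned),
as are peaks below 0.3 correlation; a near-flat log-curvature guard keeps
the integer-pixel estimate instead of an unstable refinement, and a 3×3
median-consistency pass removes outlier vectors. Rigid shifts are
recovered to ~0.03 px on rendered nuclear textures. Path integration
advects seed points through bilinearly interpolated fields (linear
extrapolation beyond the window-centre hull) and accumulates track length,
truncating at the frame border.

Limitation, established while building the simulation-coupled tests: on
movies of the *self-organising* scenario rendered from sparse tracer
nuclei, the patchwise-correlation noise floor (speckle decorrelation from
Brownian motion between frames, ~1 px/frame RMS here) exceeds the coherent
recruitment drift (~0.2 px/frame), and near maturity basin reassignment
between transient proto-foci plus aggregate-rim growth make the
"inward-toward-the-final-centroid" projection sign-indefinite. The robust
half of the science — strong, spatially local inward flow around an
attractant point source, the template mode of recruitment — is asserted in
the tests; both scenarios' radial-inflow profiles and track-length maps
are computed and reported by `analysis/07_velocimetry.py` for inspection.

## Problem sizes

Simulations use 64×64 grids (h = 1 for the RD exemplar, h = 0.5 for
chemotaxis), dt = 0.005 h and 0.02 h respectively; scans use 1,000 draws;
trajectory analyses use 20 datasets (50 for the bias-0 null) of 370 cells;
the half-life screen uses 500 transcripts; PIV validation uses 20 textures.
These sizes put every statistic comfortably past its convergence knee
while keeping a full test-suite run in a few minutes.
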
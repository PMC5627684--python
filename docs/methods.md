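# Methods

This note records the models implemented in saxskit, the defaults and why
they were chosen, what the synthetic benchmarks do and do not demonstrate,
and the numerical decisions a maintainer would want written down.

## Profiles and uncertainty propagation

A scattering profile is (q, I, σ) with strictly increasing q (Å⁻¹),
arbitrary intensity units and per-point 1σ uncertainties. Arithmetic
operations treat point errors as independent Gaussians:
averaging N profiles gives σ = √(Σσ_k²)/N, subtraction adds in quadrature,
scaling multiplies σ by |s| (offsets are treated as exact). Rebinning by a
factor m averages non-overlapping blocks (σ = √(Σσ²)/m, with a trailing
partial block averaged over its actual size); merging interpolates the
high-q curve onto the low-q grid in the overlap and averages. These
conventions are the standard ones; none is forced by the file format, so
they are stated here and enforced by the test suite.

Every operation appends exactly one layer to the profile's recursive
history (operation, parameters, parents), so a profile's full derivation
tree — e.g. an average of ten subtracted frames — survives a save/load
cycle. `.dat` files are plain three-column text; the analysis results and
the history travel as a single JSON document on trailing `#` comment lines,
invisible to third-party three-column readers. Numbers are written with 9
significant digits, which bounds round-trip error below 1e-8 relative. An
unreadable footer downgrades to a warning (foreign `.dat` files remain
loadable).

## Image reduction

Flat-detector geometry: a pixel at distance d (mm) from the beam center
scatters at 2θ = arctan(d/L) and q = 4π sin(θ)/λ. Pixels are binned into
`n_bins` (default 200) equal-width q bins spanning [0, q_corner]; the
reported bin q is the mean q of contributing pixels (less discretization
bias than bin centers), and empty bins are dropped. Bin uncertainty is
√(Σ max(counts,1))/N_pix — Poisson statistics with a one-count floor so an
empty pixel never claims zero variance. The optional solid-angle correction
multiplies each pixel by cos³(2θ) before binning (off by default).
Normalization expressions ("i0/(t*1e6)" etc.) are evaluated by a
whitelisted recursive-descent parser — numeric literals, header names,
+ − * / parentheses, log/exp/sqrt/min/max — never by a general-purpose
evaluator. Masks are rasterized from circle/rectangle/polygon specs by
pixel-center containment. Supported inputs are TIFF and whitespace text
matrices; beamline-specific formats and header dialects are out of scope
(a sidecar "key value" header file is read when present).

## Automatic Guinier fitting

`guinier_fit` is an unweighted least-squares line through ln I vs q² with
parameter variances from the fit covariance (σ_Rg = 3σ_slope/(2R_g),
σ_I0 = I0·σ_intercept). The automatic search scores candidate windows:
ten window sizes from 10 points up to the span over which the smoothed
intensity (width-5 moving mean) falls by 10× from I(q_min), stepped with a
stride of n_points/50. The score averages six terms in [0, 1] — closeness
of q_max·R_g to 1.3, smallness of q_min·R_g, the two fractional parameter
errors, r², and relative window length — with double weight on r² and
window length; fits are accepted only above a 0.6 threshold.

One guard proved necessary: windows whose fit ends beyond q_max·R_g = 1.5
are disqualified outright. r² is insensitive to the slow systematic
curvature of a globular particle's profile beyond the Guinier regime, so
without the bound the double-weighted window-length term pulls the
selection out to q·R_g ≈ 2–2.6 and biases R_g upward by ~5% on spheres;
with it the accepted ranges end at q·R_g ≈ 1.3–1.5 and the median error on
the noisy-sphere benchmark is ~2.4%. The 1.5 cutoff is the conventional
outer edge of Guinier validity for compact particles. Ties in score break
toward longer windows, then lower start index; windows containing
non-positive intensities are skipped rather than aborting the search.

## Molecular weight

- **Reference**: MW = MW_ref · (I0/c) / (I0_ref/c_ref); I(0) ∝ c·MW.
- **Absolute**: MW[g/mol] = N_A·I(0)[cm⁻¹] / (c[g/cm³]·Δρ_M²), with
  Δρ_M = r_e·(e⁻/g − ρ_solv·v̄) and protein-in-water defaults
  (3.22e23 e/g, 3.34e23 e/cm³, v̄ = 0.7425 cm³/g, r_e = 2.8179e-13 cm),
  all configurable.
- **Porod volume**: the measured curve is truncated at `qmax_cut`
  (default min(0.3 Å⁻¹, q_max)) and extended to q = 0 with the Guinier
  model I0·exp(−q²R_g²/3) on a grid spaced like the first data step; then
  Q = ∫q²I dq (trapezoid), V_p = 2π²I(0)/Q, MW = ρ·V_p with
  ρ = 0.83e-3 kDa/Å³ (≈1.37 g/cm³ protein packing). Truncating Q at finite
  q biases V_p high (≈ +14% for a sphere at q_max·R = 7.5, verified against
  adaptive quadrature of the analytic curve); a linear correction
  V_p → A + B·V_p can be supplied as a JSON table of [qmax, A, B] rows
  interpolated at `qmax_cut`. No table ships by default — published
  coefficient sets exist but were not available to transcribe verbatim, and
  inventing them would be worse than documenting the identity default.
- **Volume of correlation**: V_c = I(0)/∫qI dq over the same extended
  curve, Q_R = V_c²/R_g, MW = (Q_R/c)^k. The protein calibration
  (c = 0.1231, k = 1.0) and RNA calibration (c = 0.00934, k = 0.808) are
  the conventional literature values and produce mass in Da; results are
  reported in kDa. Both V_p and V_c are exactly invariant under intensity
  rescaling, which the tests assert to machine precision.

## Bayesian indirect Fourier transform

P(r) on n_r = 100 points over [0, D_max] with P(0) = P(D_max) = 0 is linked
to the data by I = K p, K_ij = 4πΔr·sinc(q_i r_j) with trapezoid
end-weights. For fixed (D_max, α) the solution minimizes
χ² + α·Σ(second differences)², a quadratic problem solved by its normal
equations. Model selection maximizes the Gaussian-approximation log
evidence −χ²/2 − αS + ½[ln det(αB + εI) − ln det(αB + KᵀWK)] with
ε = 1e-10·tr(B) regularizing the prior determinant, over a 15×15 grid of
D_max ∈ [2R_g, 5R_g] (from the automatic Guinier fit, overridable) ×
α log-spaced in [1, 1e10], followed by Nelder–Mead refinement in
(D_max, log α) that by construction never returns less evidence than the
best grid cell. Positivity of P(r) is deliberately not enforced — the
solver stays linear and exactly solvable — and the negative-mass fraction
is reported instead; on well-posed inputs it is ~0. Uncertainties on P(r)
come from the diagonal of (αB + KᵀWK)⁻¹. Derived quantities use trapezoid
moments; because I(0) = 4π∫P dr uses the same quadrature as K, the
normalization identity holds to machine precision. On the sphere benchmark
(R = 40 Å, 0.5% noise) the evidence maximum lands at D_max ≈ 78 Å (true
80 — the smoothness prior slightly prefers the shortest D_max that still
fits), R_g within 0.1% and reduced χ² ≈ 1.

## SEC-SAXS series

Frames are indexed 0..N−1 in load order; all profiles must share one q
grid. Buffer frames (one or more disjoint inclusive ranges) are pooled
into a single average subtracted from every frame. A window of w frames
(default 5) steps one frame at a time; each window is averaged,
auto-Guinier fitted, and — when the fit is accepted — assigned a
volume-of-correlation MW (chosen because it needs no concentration, with
the protein calibration by default). The record is stored at the window's
central frame s + w//2; the stepping itself covers frames 1–5, 2–6, 3–7, …
in 1-based terms, N−w+1 windows in all. The series (profiles, subtracted
profiles, ranges, results) serializes losslessly to a single versioned
JSON document; the per-frame CSV export carries exactly the columns
total_intensity, average_intensity, intensity_at_q, frame_number, rg,
rg_uncertainty, mw, i0, i0_uncertainty, filename. "Total intensity" is the
plain sum of I over grid points (not a q-integral).

## SVD and evolving factor analysis

The series matrix M has q along rows and frames along columns (optionally
divided elementwise by σ — exposed as `use_errors`). Component counting
uses the singular values together with the lag-1 autocorrelations
R_i = Σ_k X[k,i]X[k+1,i] of the left and right singular vectors: a
significant component needs both a singular value above 1e-3 of the
largest and smooth (autocorrelation > 0.6) vectors, which separates the
three real components of a buffer + two-species simulation from the noise
floor.

EFA rotates the rank-r truncated factors so each concentration column
vanishes outside its user-supplied frame window: C = V_r R, S = U_rΣ_r(R⁻¹)ᵀ,
S·Cᵀ ≡ U_rΣ_rV_rᵀ for any invertible R. The explicit method takes column k
of R as the smallest right singular vector of the out-of-window rows of
V_r (first nonzero entry made positive). The iterative method alternates
zeroing C outside the windows with projection back onto span(V_r),
renormalizing columns each sweep — per column this is a power iteration
whose fixed point is exactly the explicit solution, so all methods agree
at convergence. The hybrid seeds the iteration with the explicit answer
and typically converges in one sweep (vs hundreds from an identity seed),
which is the content of the tested iteration-count inequality. Convergence
is declared when the largest relative column change drops below 1e-12
(max_iter 1000). Concentration columns are sign-fixed positive at their
peak and scaled to unit maximum; the intrinsic scale ambiguity of factor
rotation means component intensities are recovered up to that per-component
scale, which correlation-based validation deliberately ignores.

## Synthetic benchmarks — what they show and what they do not

The generators produce homogeneous-sphere form factors
I(q) = I0·[3(sin x − x cos x)/x³]², x = qR (R_g = R√(3/5), D_max = 2R,
first zero at x ≈ 4.4934), the matching analytic P(r), Gaussian elution
peaks over a flat buffer, heteroscedastic Gaussian noise σ = f·I + floor,
and radially symmetric detector images. Default study conditions:
sphere R = 30 Å, I(0) = 100, q ∈ [0.005, 0.25] Å⁻¹ with 400 points and 1%
noise for Guinier benchmarks; R = 40 Å, 0.5% noise for BIFT; 100 frames
with elution centers 40/55, width 8, sphere radii 20/35 Å over a buffer of
10 for the SEC/SVD/EFA benchmarks; a 200×200-pixel detector at 1000 mm,
0.172 mm pixels, λ = 1 Å for reduction (the R = 20 Å generating sphere
keeps the whole detector below the form factor's first zero, where a
relative-recovery criterion is meaningful). Benchmark sizes are chosen so
the full suite runs in seconds on one core.

Passing these benchmarks shows the estimators are unbiased and the
algebra/bookkeeping is right under the assumed error model. It does not
demonstrate robustness to the pathologies of real data: inter-frame buffer
drift, capillary fouling, radiation damage, concentration-dependent
interparticle interference, detector nonuniformity, or aggregation tails
at low q — none of which the generators emulate. Gaussian elution shapes
are an idealization of real (often tailed) chromatographic peaks.

## Degenerate inputs and tie-breaks

Grids are "equal" within 1e-6 relative (absorbs formatting noise).
Nearest-q lookups break ties toward the lower index. Guinier fits with
non-negative slope return an invalid result rather than raising; rolling
windows whose fit fails simply carry no record. BIFT raises with a
condition-number report if the normal equations are singular anywhere it
matters, and skips singular grid cells during the evidence scan. EFA
refuses windows that leave fewer than r−1 out-of-window frames
(underdetermined rotation) and reports `converged=False` with the
iteration count when the tolerance is not reached.
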
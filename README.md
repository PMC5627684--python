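# saxskit

A scriptable Python library and command-line tool for reducing and analyzing
biological small-angle X-ray scattering (SAXS) data, including size-exclusion
chromatography coupled SAXS (SEC-SAXS).

SAXS measures the scattered intensity I(q) of macromolecules in solution as a
function of momentum transfer q = 4π sin(θ)/λ (2θ the scattering angle, λ the
wavelength, q in Å⁻¹). From a single well-subtracted profile one can extract
the radius of gyration R_g, the forward scattering I(0), the pair-distance
distribution P(r) and the maximum particle dimension D_max, and several
estimates of molecular weight. From a SEC-SAXS frame series one can follow
those parameters across an elution peak and deconvolve overlapping peaks into
the scattering of the individual species.

## What it does

- **Reduction** — radially average 2D detector images (TIFF or text matrices)
  into I(q) with Poisson counting statistics, with masking, solid-angle
  correction, expression-based normalization against image-header values, and
  JSON configuration files (`saxskit.reduction`).
- **Profiles** — a `ScatteringProfile` container (q, I, σ) with averaging,
  subtraction, merging, rebinning, interpolation, scaling and truncation,
  Gaussian error propagation, and a recursive derivation history saved in a
  JSON footer of standard three-column `.dat` files (`saxskit.core`,
  `saxskit.ops`).
- **Guinier analysis** — ln I vs q² fits, manual or automatic: candidate
  windows are scored for q_max·R_g near 1.3, small fractional errors, fit
  quality and window length, and the best window above a quality threshold is
  selected (`saxskit.guinier`).
- **Molecular weight** — four estimators: I(0) referenced to a standard,
  absolute-scale I(0), the (correctable) Porod volume
  V_p = 2π² I(0)/∫q²I dq, and the concentration-free volume of correlation
  V_c = I(0)/∫qI dq with Q_R = V_c²/R_g (`saxskit.molweight`).
- **BIFT** — a Bayesian indirect Fourier transform: P(r) regularized by a
  second-difference smoothness prior, with α and D_max chosen by maximizing
  the posterior evidence (`saxskit.bift`).
- **SEC-SAXS** — series containers, intensity traces, pooled-buffer
  subtraction, rolling-window R_g/I(0)/MW across peaks, extraction and CSV
  export (`saxskit.series`).
- **SVD / EFA** — singular-value diagnostics with singular-vector
  autocorrelations, and evolving factor analysis with three rotation methods
  (explicit, iterative, hybrid) to deconvolve overlapping elution peaks
  (`saxskit.svd_efa`).
- **Synthetic data** — analytic sphere form factors and P(r), Gaussian
  elution series and detector-image rendering, used as test oracles and
  available for fixtures (`saxskit.synthetic`).

## Worked example

```python
import numpy as np
from saxskit import auto_guinier, bift, vc_mw, synthetic

q = np.linspace(0.005, 0.25, 400)
profile = synthetic.add_noise(synthetic.sphere_profile(30.0, 100.0, q),
                              0.01, seed=1)

fit = auto_guinier(profile)
print(f"Rg   = {fit.rg:.2f} +/- {fit.rg_err:.2f} A")
print(f"I(0) = {fit.i0:.1f} +/- {fit.i0_err:.1f}")
mw = vc_mw(profile, fit)
print(f"MW(Vc) = {mw.mw:.1f} kDa")
ift = bift(profile)
print(f"Dmax = {ift.dmax:.1f} A   Rg(P(r)) = {ift.rg_pr:.2f} A   "
      f"chi2_red = {ift.chisq_reduced:.2f}")
```

prints

```
Rg   = 23.80 +/- 0.05 A
I(0) = 100.4 +/- 0.1
MW(Vc) = 57.0 kDa
Dmax = 58.0 A   Rg(P(r)) = 23.24 A   chi2_red = 0.82
```

The sample is a homogeneous sphere of radius 30 Å with 1% Gaussian noise, so
the exact targets are R_g = 30·√(3/5) = 23.24 Å, I(0) = 100 and
D_max = 60 Å: the automatic Guinier fit lands within ~2.5%, the P(r)-derived
R_g is essentially exact, D_max comes back within ~3%, and a reduced χ² near
1 says the regularized fit is statistically consistent with the added noise.

The same analyses are available from the shell:

```sh
saxskit simulate sec-overlap --seed 3 --out-dir frames/
saxskit sec frames/frame_*.dat --buffer 0:9 --buffer 90:99 --window 5 \
        --svd --efa 10:64 --efa 35:95 --method hybrid --out-dir out/
```

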
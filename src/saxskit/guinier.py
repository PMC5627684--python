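"""Guinier analysis: manual fits and an automatic optimal-range search.

At low q a globular particle scatters as
ln I(q) = ln I(0) - q^2 Rg^2 / 3, so a straight-line fit of ln I against q^2
yields the radius of gyration Rg from the slope and the forward scattering
I(0) from the intercept.  The approximation is trusted only for
q*Rg up to about 1.3, which is what the automatic search aims for.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import ScatteringProfile

__all__ = ["GuinierResult", "guinier_fit", "auto_guinier"]

MIN_WINDOW = 10          # smallest candidate window, in points
N_WINDOW_SIZES = 10      # number of candidate window sizes
QMAX_RG_TARGET = 1.3     # ideal q_max * Rg for the fitted range
QMAX_RG_LIMIT = 1.5      # fits ending beyond this q*Rg are outside the
                         # Guinier regime and are disqualified outright
SCORE_THRESHOLD = 0.6    # minimum quality score to accept an automatic fit
DECADE_RATIO = 10.0      # I(q_min)/I(q) ratio bounding the search region
SMOOTH_WIDTH = 5         # moving-mean width for the search-region bound


@dataclass
class GuinierResult:
    """Result of a Guinier fit over the inclusive index range [idx_min, idx_max]."""

    idx_min: int
    idx_max: int
    rg: float
    rg_err: float
    i0: float
    i0_err: float
    qmin_rg: float
    qmax_rg: float
    r_squared: float
    score: float = 0.0
    valid: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def invalid(cls, reason: str) -> "GuinierResult":
        return cls(0, 1, float("nan"), float("nan"), float("nan"), float("nan"),
                   float("nan"), float("nan"), float("nan"), 0.0, False, reason)


def _linefit(x: np.ndarray, y: np.ndarray):
    """Unweighted least squares y = b + s*x with parameter variances.

    Closed form rather than a polyfit call: the automatic search performs
    hundreds of fits per profile.
    """
    n = len(x)
    xm = x.mean()
    ym = y.mean()
    dx = x - xm
    sxx = np.dot(dx, dx)
    slope = np.dot(dx, y - ym) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = np.dot(resid, resid)
    sst = np.dot(y - ym, y - ym)
    # residual variance with n-2 dof; exact data gives ~0
    var = ss_res / (n - 2) if n > 2 else 0.0
    slope_var = var / sxx
    intercept_var = var * (1.0 / n + xm * xm / sxx)
    r_squared = 1.0 - ss_res / sst if sst > 0 else (1.0 if ss_res == 0 else 0.0)
    return slope, intercept, np.sqrt(slope_var), np.sqrt(intercept_var), r_squared


def guinier_fit(profile: ScatteringProfile, idx_min: int, idx_max: int) -> GuinierResult:
    """Fit ln I vs q^2 over the inclusive point range [idx_min, idx_max].

    Requires >= 3 points, all with positive intensity.  A non-negative slope
    (no Guinier decay) yields a result with ``valid=False`` rather than an
    exception.  Uncertainties come from the fit covariance by first-order
    propagation: sigma_Rg = 3*sigma_slope/(2*Rg), sigma_I0 = I0*sigma_intercept.
    """
    if not (0 <= idx_min < idx_max < len(profile)):
        raise ValueError(f"invalid index range [{idx_min}, {idx_max}]")
    if idx_max - idx_min + 1 < 3:
        raise ValueError("Guinier fit needs at least 3 points")
    i = profile.intensity[idx_min:idx_max + 1]
    q = profile.q[idx_min:idx_max + 1]
    if np.any(i <= 0):
        raise ValueError("nonpositive intensity inside the fit range")
    slope, intercept, s_err, b_err, r2 = _linefit(q**2, np.log(i))
    if slope >= 0:
        res = GuinierResult.invalid("non-negative slope: no Guinier decay")
        res.idx_min, res.idx_max = idx_min, idx_max
        res.r_squared = r2
        return res
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    rg_err = 3.0 * s_err / (2.0 * rg)
    i0_err = i0 * b_err
    return GuinierResult(
        idx_min=idx_min, idx_max=idx_max,
        rg=rg, rg_err=float(rg_err), i0=i0, i0_err=float(i0_err),
        qmin_rg=float(q[0] * rg), qmax_rg=float(q[-1] * rg),
        r_squared=float(r2), score=0.0, valid=True,
    )


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving mean with edge windows shortened to the data."""
    kernel = np.ones(width)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _search_limit(profile: ScatteringProfile) -> int:
    """Largest window size: points from q_min to the first q where the
    smoothed intensity has fallen by a factor of 10 from I(q_min)."""
    smoothed = _smooth(profile.intensity, SMOOTH_WIDTH)
    ref = smoothed[0]
    dropped = (smoothed <= 0) | (ref / np.where(smoothed > 0, smoothed, np.inf)
                                 >= DECADE_RATIO)
    hits = np.nonzero(dropped)[0]
    if len(hits) == 0:
        return len(profile)
    return int(hits[0]) + 1  # window spans indices 0..first-drop inclusive


def _score(fit: GuinierResult, window: int, w_max: int) -> float:
    """Quality score in [0, 1] for a candidate automatic fit.

    Rewards q_max*Rg near 1.3, q_min*Rg near 0, small fractional parameter
    errors, a straight fit and a long window, with double weight on the
    goodness of fit and the window length.  Fits whose range ends beyond
    q*Rg = 1.5 score zero: the Guinier approximation has broken down there,
    and without the hard bound the double-weighted window-length term drags
    the selection deep into the non-Guinier regime, biasing Rg upward on
    globular scatterers.
    """
    if not fit.valid or fit.rg <= 0:
        return 0.0
    if fit.qmax_rg > QMAX_RG_LIMIT:
        return 0.0
    s1 = 1.0 - min(1.0, abs(fit.qmax_rg - QMAX_RG_TARGET) / QMAX_RG_TARGET)
    s2 = 1.0 - min(1.0, fit.qmin_rg)
    s3 = 1.0 - min(1.0, fit.rg_err / fit.rg)
    s4 = 1.0 - min(1.0, fit.i0_err / fit.i0)
    s5 = min(1.0, max(0.0, fit.r_squared))
    s6 = (window - MIN_WINDOW) / (w_max - MIN_WINDOW) if w_max > MIN_WINDOW else 1.0
    return (s1 + s2 + s3 + s4 + 2.0 * s5 + 2.0 * s6) / 8.0


def auto_guinier(profile: ScatteringProfile, store: bool = True) -> GuinierResult:
    """Heuristic search for an optimal Guinier range.

    Candidate windows of ten sizes (from 10 points up to the span over which
    the smoothed intensity falls by 10x) are stepped along the curve with a
    stride of n_points // 50, each fitted and scored; the best-scoring window
    wins if its score exceeds 0.6, otherwise the result is flagged invalid.
    Ties break toward the longer window, then the lower start index.
    When `store` is true the accepted result is recorded under
    ``profile.analysis["guinier"]``.
    """
    n = len(profile)
    if n < 20:
        return GuinierResult.invalid("profile too short for automatic search")
    if profile.intensity[0] <= 0:
        return GuinierResult.invalid("nonpositive intensity at q_min")

    w_max = _search_limit(profile)
    if w_max < MIN_WINDOW:
        return GuinierResult.invalid(
            f"intensity decays too fast: search region only {w_max} points")
    windows = np.unique(np.linspace(MIN_WINDOW, w_max, N_WINDOW_SIZES).round()
                        .astype(int))
    step = max(1, n // 50)

    best: GuinierResult | None = None
    best_key = (-1.0, -1, 0)
    for w in windows:
        for start in range(0, n - w + 1, step):
            seg = profile.intensity[start:start + w]
            if np.any(seg <= 0):
                continue
            fit = guinier_fit(profile, start, start + w - 1)
            score = _score(fit, int(w), w_max)
            key = (score, int(w), -start)
            if fit.valid and key > best_key:
                fit.score = score
                best, best_key = fit, key
    if best is None:
        return GuinierResult.invalid("no valid candidate window")
    if best.score <= SCORE_THRESHOLD:
        best.valid = False
        best.reason = f"best score {best.score:.3f} below threshold {SCORE_THRESHOLD}"
        return best
    if store:
        profile.analysis["guinier"] = best.to_dict()
    return best
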
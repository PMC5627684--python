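"""Profile arithmetic with Gaussian uncertainty propagation.

Every operation returns a new profile whose history gains exactly one layer
recording the operation, its parameters and all parent profiles.  Input
uncertainties are treated as independent Gaussian errors, so averages scale
sigma by 1/sqrt(N) and differences add sigma in quadrature.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import HistoryRecord, ProfileError, ScatteringProfile

__all__ = [
    "average",
    "subtract",
    "scale_offset",
    "truncate",
    "rebin",
    "interpolate",
    "merge",
    "GridMismatchError",
]

GRID_RTOL = 1e-6  # relative tolerance for declaring two q grids identical


class GridMismatchError(ProfileError):
    """Raised when profiles do not share a common q grid."""


def _check_grids(profiles: Sequence[ScatteringProfile]) -> None:
    ref = profiles[0].q
    for p in profiles[1:]:
        if len(p.q) != len(ref):
            raise GridMismatchError(
                f"{p.name}: grid length {len(p.q)} != {len(ref)}"
            )
        scale = np.maximum(np.abs(ref), np.abs(p.q))
        bad = np.abs(p.q - ref) > GRID_RTOL * np.maximum(scale, 1e-300)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise GridMismatchError(
                f"{p.name}: q grid differs from {profiles[0].name} first at "
                f"index {idx} ({p.q[idx]!r} vs {ref[idx]!r})"
            )


def _derive(name, q, i, s, operation, parameters, parents) -> ScatteringProfile:
    history = HistoryRecord(
        operation=operation,
        parameters=parameters,
        parents=[(p.name, p.history) for p in parents],
    )
    return ScatteringProfile(name=name, q=q, intensity=i, sigma=s, history=history)


def average(profiles: Sequence[ScatteringProfile]) -> ScatteringProfile:
    """Pointwise mean of >= 2 profiles on a common grid.

    sigma_avg = sqrt(sum sigma_k^2) / N, the standard error of a mean of
    independent Gaussian measurements with stated per-point uncertainties.
    """
    if len(profiles) < 2:
        raise ValueError("average needs at least 2 profiles")
    _check_grids(profiles)
    i = np.mean([p.intensity for p in profiles], axis=0)
    s = np.sqrt(np.sum([p.sigma**2 for p in profiles], axis=0)) / len(profiles)
    return _derive(
        f"avg_{profiles[0].name}", profiles[0].q.copy(), i, s,
        "average", {"n_profiles": len(profiles)}, profiles,
    )


def subtract(a: ScatteringProfile, b: ScatteringProfile) -> ScatteringProfile:
    """a - b with quadrature uncertainties (e.g. buffer subtraction)."""
    _check_grids([a, b])
    i = a.intensity - b.intensity
    s = np.sqrt(a.sigma**2 + b.sigma**2)
    return _derive(f"{a.name}_sub_{b.name}", a.q.copy(), i, s, "subtract", {}, [a, b])


def scale_offset(p: ScatteringProfile, scale: float, offset: float = 0.0) -> ScatteringProfile:
    """I' = scale*I + offset; sigma scales by |scale| (offset is exact)."""
    if scale == 0:
        raise ValueError("scale must be nonzero")
    return _derive(
        p.name, p.q.copy(), scale * p.intensity + offset, abs(scale) * p.sigma,
        "scale_offset", {"scale": scale, "offset": offset}, [p],
    )


def truncate(p: ScatteringProfile, qmin: float, qmax: float) -> ScatteringProfile:
    """Keep points with qmin <= q <= qmax; at least 2 must survive."""
    if qmin >= qmax:
        raise ValueError("qmin must be < qmax")
    keep = (p.q >= qmin) & (p.q <= qmax)
    if np.count_nonzero(keep) < 2:
        raise ProfileError(
            f"truncation to [{qmin}, {qmax}] leaves {np.count_nonzero(keep)} points"
        )
    return _derive(
        p.name, p.q[keep], p.intensity[keep], p.sigma[keep],
        "truncate", {"qmin": qmin, "qmax": qmax}, [p],
    )


def rebin(p: ScatteringProfile, factor: int) -> ScatteringProfile:
    """Average consecutive non-overlapping blocks of `factor` points.

    q and I become block means; sigma = sqrt(sum sigma^2)/block_size.  A
    trailing partial block is averaged over its actual size.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("rebin factor must be >= 1")
    if factor == 1:
        return _derive(
            p.name, p.q.copy(), p.intensity.copy(), p.sigma.copy(),
            "rebin", {"factor": 1}, [p],
        )
    n = len(p)
    edges = np.arange(0, n + factor, factor)
    edges[-1] = min(edges[-1], n)
    edges = np.unique(edges)
    q, i, s = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        size = b - a
        q.append(p.q[a:b].mean())
        i.append(p.intensity[a:b].mean())
        s.append(np.sqrt(np.sum(p.sigma[a:b] ** 2)) / size)
    return _derive(
        p.name, np.array(q), np.array(i), np.array(s),
        "rebin", {"factor": factor}, [p],
    )


def interpolate(p: ScatteringProfile, reference_q) -> ScatteringProfile:
    """Linear interpolation of I and sigma onto `reference_q` (no extrapolation)."""
    ref = np.asarray(reference_q, dtype=float)
    if ref.min() < p.q[0] or ref.max() > p.q[-1]:
        raise ProfileError(
            f"reference grid [{ref.min()}, {ref.max()}] extends outside the "
            f"data range [{p.q[0]}, {p.q[-1]}]"
        )
    i = np.interp(ref, p.q, p.intensity)
    s = np.interp(ref, p.q, p.sigma)
    return _derive(
        p.name, ref.copy(), i, s,
        "interpolate", {"n_points": len(ref)}, [p],
    )


def merge(low: ScatteringProfile, high: ScatteringProfile) -> ScatteringProfile:
    """Merge a low-q and a high-q profile into one curve.

    In the overlap region the high-q profile is interpolated onto the low-q
    grid and averaged with it (sigma in quadrature over 2); outside the
    overlap, points are copied unchanged.  The ranges must overlap or be
    adjacent (gap no larger than the coarser grid spacing).
    """
    if low.q[0] >= high.q[0]:
        raise ProfileError("`low` must start at smaller q than `high`")
    max_dq = max(np.max(np.diff(low.q)), np.max(np.diff(high.q)))
    if high.q[0] > low.q[-1] + max_dq:
        raise ProfileError(
            f"gap between profiles: low ends at {low.q[-1]}, high starts at {high.q[0]}"
        )
    overlap = low.q >= high.q[0]
    q_lo, i_lo, s_lo = low.q[~overlap], low.intensity[~overlap], low.sigma[~overlap]
    if np.any(overlap) and high.q[0] <= low.q[-1]:
        qo = low.q[overlap]
        # clip to high's actual range so interpolation never extrapolates
        inside = qo <= high.q[-1]
        qo_in = qo[inside]
        ih = np.interp(qo_in, high.q, high.intensity)
        sh = np.interp(qo_in, high.q, high.sigma)
        io = 0.5 * (low.intensity[overlap][inside] + ih)
        so = np.sqrt(low.sigma[overlap][inside] ** 2 + sh**2) / 2
        q_ov, i_ov, s_ov = qo_in, io, so
        tail = high.q > low.q[-1]
    else:
        q_ov = np.array([])
        i_ov = s_ov = q_ov
        tail = np.ones(len(high.q), dtype=bool)
    q = np.concatenate([q_lo, q_ov, high.q[tail]])
    i = np.concatenate([i_lo, i_ov, high.intensity[tail]])
    s = np.concatenate([s_lo, s_ov, high.sigma[tail]])
    return _derive(
        f"merge_{low.name}_{high.name}", q, i, s, "merge", {}, [low, high],
    )
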
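"""SVD diagnostics and evolving factor analysis (EFA) deconvolution.

A SEC-SAXS series forms a matrix M (rows = q points, columns = frames).
The number of singular values above the noise floor counts the independent
scatterers; the autocorrelation R_i = sum_k X[k, i] X[k+1, i] of each
singular vector separates smooth signal vectors (R near 1) from noise.

EFA deconvolves overlapping elution peaks: forward/backward singular-value
traces locate where each component enters and leaves the series, and the
truncated SVD factors are then rotated so that each concentration column is
zero outside its component's frame window.  Three rotation methods are
provided: the explicit null-space construction, an alternating-projection
iteration, and a hybrid that seeds the iteration with the explicit answer
(which converges in fewer iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HistoryRecord, ScatteringProfile

__all__ = [
    "SVDResult",
    "EFAResult",
    "svd_profiles",
    "efa_traces",
    "efa_rotate",
    "efa",
    "profiles_matrix",
]


@dataclass
class SVDResult:
    singular_values: np.ndarray
    left_autocorr: np.ndarray
    right_autocorr: np.ndarray
    U: np.ndarray
    V: np.ndarray  # columns are right singular vectors

    def n_significant(self, sv_floor_ratio: float = 1e-3,
                      autocorr_min: float = 0.6) -> int:
        """Count components: singular value above `sv_floor_ratio` of the
        largest and both singular-vector autocorrelations above
        `autocorr_min` (smooth, not noise-like)."""
        s = self.singular_values
        keep = (s > sv_floor_ratio * s[0]) \
            & (self.left_autocorr > autocorr_min) \
            & (self.right_autocorr > autocorr_min)
        return int(np.count_nonzero(keep))


def _autocorr(X: np.ndarray) -> np.ndarray:
    """Per-column lag-1 autocorrelation sum_k X[k, i] X[k+1, i]."""
    return np.sum(X[:-1, :] * X[1:, :], axis=0)


def profiles_matrix(profiles, use_errors: bool = False):
    """Stack profiles into (M, sigma) with columns = frames.

    With `use_errors`, each matrix element is divided by its uncertainty so
    the SVD weights points by statistical significance.
    """
    from . import ops

    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ops._check_grids(profiles)
    M = np.column_stack([p.intensity for p in profiles])
    S = np.column_stack([p.sigma for p in profiles])
    if use_errors:
        M = M / np.where(S > 0, S, 1.0)
    return M, S


def svd_profiles(profiles, use_errors: bool = False) -> SVDResult:
    """Full SVD of a profile stack with singular-vector autocorrelations."""
    M, _ = profiles_matrix(profiles, use_errors)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    return SVDResult(
        singular_values=s,
        left_autocorr=_autocorr(U),
        right_autocorr=_autocorr(V),
        U=U, V=V,
    )


def efa_traces(matrix: np.ndarray, k: int = 3):
    """Forward and backward evolving-factor traces.

    forward[j] holds the top-k singular values of columns 0..j; backward[j]
    those of columns j..N-1.  When a submatrix has fewer than k singular
    values the missing entries are zero.  A component entering at frame f
    lifts the corresponding forward trace above its noise plateau at j >= f.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    M = np.asarray(matrix, dtype=float)
    n = M.shape[1]
    forward = np.zeros((n, k))
    backward = np.zeros((n, k))
    for j in range(n):
        sf = np.linalg.svd(M[:, : j + 1], compute_uv=False)
        forward[j, : min(k, len(sf))] = sf[:k]
        sb = np.linalg.svd(M[:, j:], compute_uv=False)
        backward[j, : min(k, len(sb))] = sb[:k]
    return forward, backward


@dataclass
class EFAResult:
    forward_trace: np.ndarray
    backward_trace: np.ndarray
    n_components: int
    ranges: list
    concentrations: np.ndarray   # frames x components, unit peak maximum
    profile_matrix: np.ndarray   # q points x components
    method: str
    iterations: int
    converged: bool
    mean_chisq: float
    components: list = field(default_factory=list)  # ScatteringProfile list

    def reconstruction(self) -> np.ndarray:
        return self.profile_matrix @ self.concentrations.T


def _window_masks(ranges, n_frames: int) -> list:
    masks = []
    for a, b in ranges:
        a, b = int(a), int(b)
        if not (0 <= a <= b < n_frames):
            raise ValueError(f"component range ({a}, {b}) outside frames [0, {n_frames - 1}]")
        m = np.zeros(n_frames, dtype=bool)
        m[a : b + 1] = True
        masks.append(m)
    return masks


def _explicit_rotation(Vr: np.ndarray, masks) -> np.ndarray:
    """Each rotation column is the unit vector minimizing the concentration
    outside its component's window: the smallest right singular vector of
    the out-of-window rows of Vr."""
    r = Vr.shape[1]
    R = np.zeros((r, r))
    for k, mask in enumerate(masks):
        Z = Vr[~mask, :]
        if Z.shape[0] < r - 1:
            raise ValueError(
                f"component {k}: only {Z.shape[0]} out-of-window frames; "
                f"need at least {r - 1} to determine the rotation")
        _, _, Zt = np.linalg.svd(Z, full_matrices=True)
        x = Zt[-1, :]
        nz = np.nonzero(np.abs(x) > 1e-14)[0]
        if len(nz) and x[nz[0]] < 0:
            x = -x
        R[:, k] = x
    return R


def _iterate_rotation(Vr: np.ndarray, masks, R0: np.ndarray,
                      tol: float, max_iter: int):
    """Alternating projection: zero concentrations outside each window, then
    project back onto the span of Vr; columns are renormalized each sweep.
    Stops when the largest relative column change drops below `tol`."""
    R = R0.copy()
    norms = np.linalg.norm(R, axis=0)
    if np.any(norms == 0):
        raise ValueError("starting rotation has a zero column")
    R = R / norms
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        C = Vr @ R
        for k, mask in enumerate(masks):
            C[~mask, k] = 0.0
        R_new = Vr.T @ C
        norms = np.linalg.norm(R_new, axis=0)
        if np.any(norms < 1e-300):
            raise ValueError("rotation column collapsed to zero during iteration")
        R_new = R_new / norms
        # sign-align columns before measuring the change
        signs = np.sign(np.sum(R_new * R, axis=0))
        signs[signs == 0] = 1.0
        R_new = R_new * signs
        change = np.max(np.linalg.norm(R_new - R, axis=0))
        R = R_new
        if change < tol:
            converged = True
            break
    return R, iterations, converged


def efa_rotate(
    matrix: np.ndarray,
    ranges,
    method: str = "hybrid",
    tol: float = 1e-12,
    max_iter: int = 1000,
    sigma: np.ndarray | None = None,
    trace_k: int | None = None,
) -> EFAResult:
    """Rotate truncated SVD factors into concentrations and profiles.

    `ranges` gives each component's inclusive frame window; concentrations
    are forced (approximately) to zero outside.  With truncated factors
    U_r, S_r, V_r, an invertible r x r rotation R gives concentrations
    C = V_r R and profiles P = U_r S_r (R^-1)^T so that P C^T reproduces the
    truncated matrix exactly.  Methods: "explicit" (null-space construction),
    "iterative" (alternating projection from an identity seed), "hybrid"
    (iteration seeded with the explicit answer).  Each concentration column
    is sign-fixed positive at its peak and scaled to unit maximum, the scale
    being absorbed into the profile matrix.
    """
    M = np.asarray(matrix, dtype=float)
    n_q, n_frames = M.shape
    r = len(ranges)
    if r < 1:
        raise ValueError("need at least one component range")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if r > np.sum(s > 1e-12 * s[0]):
        raise ValueError(f"{r} components requested but matrix rank is lower")
    Ur, sr, Vr = U[:, :r], s[:r], Vt[:r, :].T
    masks = _window_masks(ranges, n_frames)

    iterations = 0
    converged = True
    if method == "explicit":
        R = _explicit_rotation(Vr, masks)
    elif method == "iterative":
        R, iterations, converged = _iterate_rotation(
            Vr, masks, np.eye(r), tol, max_iter)
    elif method == "hybrid":
        R0 = _explicit_rotation(Vr, masks)
        R, iterations, converged = _iterate_rotation(Vr, masks, R0, tol, max_iter)
    else:
        raise ValueError(f"unknown rotation method {method!r}")

    if np.linalg.cond(R) > 1e12:
        raise np.linalg.LinAlgError("rotation matrix is (near-)singular")

    # sign/scale convention: each concentration peaks positive at 1
    C = Vr @ R
    for k in range(r):
        peak = np.argmax(np.abs(C[:, k]))
        factor = C[peak, k]
        if factor == 0:
            raise np.linalg.LinAlgError(f"component {k} has zero concentration")
        R[:, k] /= factor
    C = Vr @ R
    P = Ur @ np.diag(sr) @ np.linalg.inv(R).T

    recon = P @ C.T
    if sigma is None:
        sig = np.ones_like(M)
    else:
        sig = np.where(np.asarray(sigma) > 0, np.asarray(sigma), 1.0)
    mean_chisq = float(np.mean(((M - recon) / sig) ** 2))

    k_trace = trace_k if trace_k is not None else r + 1
    forward, backward = efa_traces(M, k=k_trace)
    return EFAResult(
        forward_trace=forward, backward_trace=backward,
        n_components=r, ranges=[tuple(rr) for rr in ranges],
        concentrations=C, profile_matrix=P,
        method=method, iterations=iterations, converged=converged,
        mean_chisq=mean_chisq,
    )


def efa(profiles, ranges, method: str = "hybrid", tol: float = 1e-12,
        max_iter: int = 1000, use_errors_chisq: bool = True) -> EFAResult:
    """EFA on a list of profiles; components come back as ScatteringProfile
    objects on the shared q grid (uncertainties are not propagated through
    the rotation and are set to zero)."""
    profiles = list(profiles)
    M, S = profiles_matrix(profiles, use_errors=False)
    result = efa_rotate(M, ranges, method=method, tol=tol, max_iter=max_iter,
                        sigma=S if use_errors_chisq else None)
    q = profiles[0].q
    for k in range(result.n_components):
        intensity = result.profile_matrix[:, k]
        result.components.append(ScatteringProfile(
            name=f"efa_component_{k}", q=q.copy(), intensity=intensity,
            sigma=np.zeros_like(q),
            history=HistoryRecord("efa_rotate", {
                "method": method, "range": list(result.ranges[k]),
                "n_components": result.n_components,
            }),
        ))
    return result
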
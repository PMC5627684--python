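"""Synthetic SAXS data: analytic profiles, noise, elution series, images.

The generators double as independent oracles for the analysis modules: the
sphere form factor and its pair-distance distribution are closed-form, so
recovered Rg, Dmax, I(0) and deconvolved component profiles can be checked
against exact targets.  All randomness flows through numpy Generators seeded
explicitly, so every output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HistoryRecord, ScatteringProfile
from .reduction import DetectorGeometry, _pixel_q_map

__all__ = [
    "ComponentSpec",
    "sphere_profile",
    "sphere_pr",
    "add_noise",
    "simulate_sec",
    "simulate_image",
]


def sphere_profile(radius: float, i0: float, q_grid, name: str = "sphere") -> ScatteringProfile:
    """Scattering of a homogeneous sphere of the given radius (Angstrom).

    I(q) = i0 * [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2, with I(0) = i0.
    The radius of gyration is R*sqrt(3/5) and Dmax = 2R.  Uncertainties are
    zero; use :func:`add_noise` for noisy realizations.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    q = np.asarray(q_grid, dtype=float)
    x = q * radius
    amp = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    amp[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    amp[small] = 1.0 - x[small] ** 2 / 10.0  # series limit, exact to O(x^4)
    return ScatteringProfile(
        name=name, q=q, intensity=i0 * amp**2, sigma=np.zeros_like(q),
        history=HistoryRecord("simulate_sphere", {"radius": radius, "i0": i0}),
    )


def sphere_pr(radius: float, n_points: int = 101, i0: float = 1.0):
    """Pair-distance distribution of a homogeneous sphere.

    p(r) is proportional to r^2 (1 - 1.5 t + 0.5 t^3) with t = r/Dmax on
    [0, Dmax = 2R], scaled so that 4*pi * integral p dr = i0.  Returns
    (r, p) arrays.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    dmax = 2.0 * radius
    r = np.linspace(0.0, dmax, n_points)
    t = r / dmax
    p = r**2 * (1.0 - 1.5 * t + 0.5 * t**3)
    norm = 4.0 * np.pi * np.trapezoid(p, r)
    return r, p * (i0 / norm)


def add_noise(
    profile: ScatteringProfile, frac: float, floor: float = 0.0, seed: int = 0
) -> ScatteringProfile:
    """Gaussian heteroscedastic noise: sigma = frac*|I| + floor.

    Matches the error model the downstream analyses assume (a stated 1-sigma
    per point); deterministic for a fixed seed.
    """
    if frac < 0 or floor < 0:
        raise ValueError("frac and floor must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = frac * np.abs(profile.intensity) + floor
    noisy = profile.intensity + rng.standard_normal(len(profile)) * sigma
    return ScatteringProfile(
        name=f"{profile.name}_noisy", q=profile.q.copy(), intensity=noisy,
        sigma=sigma,
        history=HistoryRecord("add_noise", {"frac": frac, "floor": floor,
                                            "seed": seed},
                              parents=[(profile.name, profile.history)]),
    )


@dataclass
class ComponentSpec:
    """One eluting species: its profile and a Gaussian elution peak."""

    profile: ScatteringProfile
    elution_center: float  # frame index of the peak
    elution_width: float   # Gaussian sigma, in frames
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.elution_width <= 0:
            raise ValueError("elution_width must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def concentration(self, frames: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -((frames - self.elution_center) ** 2) / (2.0 * self.elution_width**2)
        )


def simulate_sec(
    components,
    buffer_profile: ScatteringProfile,
    n_frames: int,
    noise: float = 0.01,
    floor: float = 0.0,
    seed: int = 0,
) -> list[ScatteringProfile]:
    """A SEC-SAXS frame series: buffer plus Gaussian elution peaks.

    Frame t scatters buffer(q) + sum_k c_k(t) * I_k(q) with Gaussian elution
    concentrations c_k, then per-frame Gaussian noise with
    sigma = noise*|I| + floor.  All component profiles must share the buffer's
    q grid.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    q = buffer_profile.q
    for comp in components:
        if len(comp.profile.q) != len(q) or not np.allclose(comp.profile.q, q):
            raise ValueError("component profiles must share the buffer q grid")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames, dtype=float)
    out = []
    for t in range(n_frames):
        i_t = buffer_profile.intensity.copy()
        for comp in components:
            i_t = i_t + comp.concentration(frames[t : t + 1])[0] * comp.profile.intensity
        sigma = noise * np.abs(i_t) + floor
        i_obs = i_t + rng.standard_normal(len(q)) * sigma
        out.append(ScatteringProfile(
            name=f"frame_{t:04d}", q=q.copy(), intensity=i_obs,
            sigma=np.where(sigma > 0, sigma, 0.0),
            history=HistoryRecord("simulate_sec_frame", {"frame": t, "seed": seed}),
        ))
    return out


def simulate_image(
    profile: ScatteringProfile,
    geometry: DetectorGeometry,
    shape: tuple[int, int],
    exposure: float = 1.0,
    mode: str = "expectation",
    seed: int = 0,
) -> np.ndarray:
    """Render a radially symmetric detector image from a 1D profile.

    Expected counts per pixel are exposure * I(q(pixel)), with I linearly
    interpolated and clipped to the profile's edge values outside its q
    range.  mode="expectation" returns the noiseless expectations (useful as
    an integration oracle); mode="poisson" samples counts with the seed.
    """
    qmap, _ = _pixel_q_map(geometry, shape)
    expected = exposure * np.interp(
        qmap, profile.q, profile.intensity,
        left=profile.intensity[0], right=profile.intensity[-1],
    )
    if mode == "expectation":
        return expected
    if mode == "poisson":
        rng = np.random.default_rng(seed)
        return rng.poisson(np.maximum(expected, 0.0)).astype(float)
    raise ValueError(f"unknown mode {mode!r}")
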
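"""Detector image to 1D profile: q map, masking, radial average, normalization.

Geometry follows the usual flat-detector convention: for a pixel at radial
distance d (mm) from the beam center, the scattering angle is
2*theta = arctan(d / distance) and q = 4*pi*sin(theta)/lambda in 1/Angstrom.
Image coordinates are (x = column, y = row), 0-based, with pixel centers at
integer coordinates.

Counting statistics: the uncertainty of a radial bin is
sqrt(sum max(counts, 1)) / N_pixels, i.e. Poisson errors with a floor of one
count per pixel so that empty pixels never claim zero uncertainty.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import HistoryRecord, ScatteringProfile

__all__ = [
    "DetectorGeometry",
    "ReductionConfig",
    "q_of_pixel",
    "radial_average",
    "evaluate_normalization",
    "make_mask",
    "reduce_image",
    "load_image",
    "load_header",
    "load_config",
    "save_config",
    "ExpressionError",
    "ConfigError",
]


class ExpressionError(ValueError):
    """Raised for invalid normalization expressions."""


class ConfigError(ValueError):
    """Raised when a reduction config fails validation."""


@dataclass
class DetectorGeometry:
    """Flat-detector geometry and beam parameters.

    beam_center_x/y are in pixels (continuous, x = column, y = row),
    distance is the sample-detector distance in mm, wavelength in Angstrom,
    pixel_size in mm.  When solid_angle_correction is on, each pixel's
    intensity is multiplied by cos^3(2*theta) before binning.
    """

    beam_center_x: float
    beam_center_y: float
    distance: float
    wavelength: float
    pixel_size: float
    solid_angle_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("distance", "wavelength", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"geometry field {name!r} must be > 0")

    def to_dict(self) -> dict:
        return {
            "beam_center_x": self.beam_center_x,
            "beam_center_y": self.beam_center_y,
            "distance": self.distance,
            "wavelength": self.wavelength,
            "pixel_size": self.pixel_size,
            "solid_angle_correction": self.solid_angle_correction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DetectorGeometry":
        try:
            return cls(**{k: d[k] for k in (
                "beam_center_x", "beam_center_y", "distance", "wavelength",
                "pixel_size")}, solid_angle_correction=bool(
                    d.get("solid_angle_correction", False)))
        except KeyError as exc:
            raise ConfigError(f"geometry missing field {exc.args[0]!r}") from None


def q_of_pixel(geometry: DetectorGeometry, x, y):
    """Momentum transfer q (1/A) of pixel(s) at column x, row y.

    Vectorized: x and y may be arrays.  q = 4*pi*sin(arctan(d/L)/2)/lambda
    with d the in-plane distance from the beam center in mm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = geometry.pixel_size * np.hypot(x - geometry.beam_center_x,
                                       y - geometry.beam_center_y)
    two_theta = np.arctan2(d, geometry.distance)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / geometry.wavelength
    if q.ndim == 0:
        return float(q)
    return q


def _pixel_q_map(geometry: DetectorGeometry, shape) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = geometry.pixel_size * np.hypot(xx - geometry.beam_center_x,
                                       yy - geometry.beam_center_y)
    two_theta = np.arctan2(d, geometry.distance)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / geometry.wavelength
    return q, two_theta


def radial_average(
    image: np.ndarray,
    geometry: DetectorGeometry,
    mask: np.ndarray | None = None,
    n_bins: int = 200,
    name: str = "integrated",
) -> ScatteringProfile:
    """Radially average a detector image into I(q) with counting statistics.

    Pixels are assigned to `n_bins` equal-width q bins spanning [0, q_max]
    where q_max is the largest q on the detector.  Per bin the intensity is
    the mean pixel value (after the optional cos^3(2theta) solid-angle factor)
    and the reported q is the mean q of the contributing pixels.  Empty bins
    are dropped.  `mask` is boolean with True = excluded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if mask is None:
        mask = np.zeros(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if mask.all():
        raise ValueError("all pixels are masked")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    qmap, two_theta = _pixel_q_map(geometry, image.shape)
    valid = ~mask
    qv = qmap[valid]
    counts = image[valid]
    iv = counts.copy()
    if geometry.solid_angle_correction:
        iv = iv * np.cos(two_theta[valid]) ** 3
    var = np.maximum(counts, 1.0)  # Poisson variance with a 1-count floor

    qmax = qmap.max()
    idx = np.minimum((qv / qmax * n_bins).astype(int), n_bins - 1)
    npix = np.bincount(idx, minlength=n_bins)
    isum = np.bincount(idx, weights=iv, minlength=n_bins)
    vsum = np.bincount(idx, weights=var, minlength=n_bins)
    qsum = np.bincount(idx, weights=qv, minlength=n_bins)

    keep = npix > 0
    # the q=0 bin contains the beam-center pixel; keep it unless q degenerates
    q_out = qsum[keep] / npix[keep]
    i_out = isum[keep] / npix[keep]
    s_out = np.sqrt(vsum[keep]) / npix[keep]
    # drop leading bins with non-increasing q (can only happen at q == 0)
    order_ok = np.concatenate([[True], np.diff(q_out) > 0])
    while not order_ok.all():
        q_out, i_out, s_out = q_out[order_ok], i_out[order_ok], s_out[order_ok]
        order_ok = np.concatenate([[True], np.diff(q_out) > 0])
    return ScatteringProfile(
        name=name, q=q_out, intensity=i_out, sigma=s_out,
        history=HistoryRecord("integrate", {"n_bins": n_bins}),
    )


# --- safe arithmetic-expression evaluation for normalization ---------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z_0-9]*)"
    r"|(?P<op>[-+*/(),]))"
)

_FUNCTIONS = {
    "log": (1, math.log),
    "exp": (1, math.exp),
    "sqrt": (1, math.sqrt),
    "min": (2, min),
    "max": (2, max),
}


def _tokenize(expression: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            raise ExpressionError(
                f"disallowed token at position {pos}: {expression[pos:]!r}"
            )
        if m.group("num") is not None:
            tokens.append(("num", m.group("num")))
        elif m.group("name") is not None:
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    tokens.append(("end", ""))
    return tokens


class _Parser:
    """Recursive-descent evaluator for + - * / parentheses and a small
    whitelist of functions; names resolve against the image header only."""

    def __init__(self, tokens, header: Mapping[str, float]):
        self.tokens = tokens
        self.pos = 0
        self.header = header

    def peek(self):
        return self.tokens[self.pos]

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, value):
        kind, text = self.next()
        if kind != "op" or text != value:
            raise ExpressionError(f"expected {value!r}, got {text!r}")

    def parse(self) -> float:
        value = self.expr()
        kind, text = self.next()
        if kind != "end":
            raise ExpressionError(f"unexpected trailing token {text!r}")
        return value

    def expr(self) -> float:
        value = self.term()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            _, op = self.next()
            rhs = self.term()
            value = value + rhs if op == "+" else value - rhs
        return value

    def term(self) -> float:
        value = self.unary()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            _, op = self.next()
            rhs = self.unary()
            if op == "*":
                value = value * rhs
            else:
                if rhs == 0:
                    raise ExpressionError("division by zero in normalization expression")
                value = value / rhs
        return value

    def unary(self) -> float:
        if self.peek() == ("op", "-"):
            self.next()
            return -self.unary()
        if self.peek() == ("op", "+"):
            self.next()
            return self.unary()
        return self.atom()

    def atom(self) -> float:
        kind, text = self.next()
        if kind == "num":
            return float(text)
        if kind == "name":
            if text in _FUNCTIONS:
                nargs, fn = _FUNCTIONS[text]
                self.expect("(")
                args = [self.expr()]
                while self.peek() == ("op", ","):
                    self.next()
                    args.append(self.expr())
                self.expect(")")
                if len(args) != nargs:
                    raise ExpressionError(
                        f"{text}() takes {nargs} argument(s), got {len(args)}"
                    )
                try:
                    return float(fn(*args))
                except ValueError as exc:
                    raise ExpressionError(f"domain error in {text}(): {exc}") from None
            if text in self.header:
                return float(self.header[text])
            raise ExpressionError(
                f"unknown name {text!r}; available header names: "
                f"{sorted(self.header)}"
            )
        if kind == "op" and text == "(":
            value = self.expr()
            self.expect(")")
            return value
        raise ExpressionError(f"unexpected token {text!r}")


def evaluate_normalization(expression: str, header: Mapping[str, float]) -> float:
    """Evaluate an arithmetic normalization expression against header values.

    Only numeric literals, header names, + - * / parentheses and the
    functions log/exp/sqrt/min/max are allowed; anything else raises
    :class:`ExpressionError`.  The caller divides the profile by the result.
    """
    return _Parser(_tokenize(expression), header).parse()


# --- masks ------------------------------------------------------------------

def _polygon_contains(vertices: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Even-odd-rule point-in-polygon test on pixel centers (vectorized)."""
    inside = np.zeros(xx.shape, dtype=bool)
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        crosses = (y1 > yy) != (y2 > yy)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (yy - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xx < xint)
    return inside


def make_mask(shape, regions: Sequence[Mapping], invert: bool = False) -> np.ndarray:
    """Rasterize a union of circle/rectangle/polygon regions into a mask.

    A pixel is excluded (True) when its center lies inside any region.
    Region specs are dicts:
      {"type": "circle", "center": [x, y], "radius": r}
      {"type": "rectangle", "xmin": .., "xmax": .., "ymin": .., "ymax": ..}
      {"type": "polygon", "vertices": [[x, y], ...]}
    `invert` flips the result (mask everything outside the union).
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(shape, dtype=bool)
    for region in regions:
        kind = region.get("type")
        if kind == "circle":
            cx, cy = region["center"]
            r = float(region["radius"])
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        elif kind == "rectangle":
            mask |= (
                (xx >= region["xmin"]) & (xx <= region["xmax"])
                & (yy >= region["ymin"]) & (yy <= region["ymax"])
            )
        elif kind == "polygon":
            verts = np.asarray(region["vertices"], dtype=float)
            mask |= _polygon_contains(verts, xx, yy)
        else:
            raise ValueError(f"unknown mask region type {kind!r}")
    if invert:
        mask = ~mask
    return mask


# --- config -----------------------------------------------------------------

@dataclass
class ReductionConfig:
    """All settings needed to turn an image into a normalized profile."""

    geometry: DetectorGeometry
    mask_regions: list = field(default_factory=list)
    mask_invert: bool = False
    normalization: str = "1"
    n_bins: int = 200
    absolute_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        try:
            _tokenize(self.normalization)
        except ExpressionError as exc:
            raise ConfigError(f"normalization expression invalid: {exc}") from None

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "mask_regions": list(self.mask_regions),
            "mask_invert": self.mask_invert,
            "normalization": self.normalization,
            "n_bins": self.n_bins,
            "absolute_scale": self.absolute_scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReductionConfig":
        if "geometry" not in d:
            raise ConfigError("config missing field 'geometry'")
        return cls(
            geometry=DetectorGeometry.from_dict(d["geometry"]),
            mask_regions=list(d.get("mask_regions", [])),
            mask_invert=bool(d.get("mask_invert", False)),
            normalization=str(d.get("normalization", "1")),
            n_bins=int(d.get("n_bins", 200)),
            absolute_scale=float(d.get("absolute_scale", 1.0)),
        )


def save_config(config: ReductionConfig, path) -> None:
    with open(str(path), "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def load_config(path) -> ReductionConfig:
    with open(str(path), "r", encoding="utf-8") as fh:
        return ReductionConfig.from_dict(json.load(fh))


# --- image + header loading -------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a TIFF (.tif/.tiff) or whitespace-separated text matrix."""
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.atleast_2d(np.loadtxt(path, dtype=float))


def load_header(path) -> dict:
    """Parse a sidecar header file of 'key value' lines into a mapping."""
    header: dict[str, float] = {}
    with open(str(path), "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) == 2:
                try:
                    header[parts[0]] = float(parts[1])
                except ValueError:
                    continue
    return header


def reduce_image(
    image,
    config: ReductionConfig,
    header: Mapping[str, float] | None = None,
    name: str | None = None,
) -> ScatteringProfile:
    """Full reduction: integrate, normalize, apply the absolute scale.

    `image` may be an array or a path (TIFF or text matrix; a sidecar
    '<image>.hdr' file of 'key value' lines is read as the header when
    present and no header mapping is given).
    """
    if isinstance(image, (str, os.PathLike)):
        path = str(image)
        if header is None:
            sidecar = path + ".hdr"
            header = load_header(sidecar) if os.path.exists(sidecar) else {}
        if name is None:
            name = os.path.splitext(os.path.basename(path))[0]
        image = load_image(path)
    header = dict(header or {})
    name = name or "integrated"

    mask = make_mask(image.shape, config.mask_regions, config.mask_invert) \
        if config.mask_regions or config.mask_invert else None
    profile = radial_average(image, config.geometry, mask, config.n_bins, name=name)
    norm = evaluate_normalization(config.normalization, header)
    if norm == 0:
        raise ExpressionError("normalization evaluated to zero")
    scale = config.absolute_scale / norm
    profile.intensity *= scale
    profile.sigma *= abs(scale)
    profile.history = HistoryRecord(
        "integrate",
        {
            "n_bins": config.n_bins,
            "normalization": config.normalization,
            "normalization_value": norm,
            "absolute_scale": config.absolute_scale,
            "geometry": config.geometry.to_dict(),
        },
    )
    return profile
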
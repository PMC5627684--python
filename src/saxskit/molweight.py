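"""Molecular-weight estimation from scattering profiles by four methods.

(i)   reference:  scale I(0)/c against a measured standard of known MW;
(ii)  absolute:   I(0) on an absolute scale (1/cm) plus the scattering
                  contrast per unit mass of a protein in water;
(iii) porod:      the (optionally corrected) Porod volume Vp = 2*pi^2*I(0)/Q
                  with Q = integral of q^2 I(q), times a packing density;
(iv)  vc:         the volume of correlation Vc = I(0)/integral of q*I(q) and
                  the mass parameter QR = Vc^2/Rg with a power-law
                  calibration per molecule class.

Methods (iii) and (iv) are concentration-free: both are invariant under a
rescaling of the intensity.  Both extrapolate the measured curve to q = 0
with the Guinier model before integrating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.constants import Avogadro

from .core import ScatteringProfile
from .guinier import GuinierResult

__all__ = [
    "MWResult",
    "ContrastParams",
    "mw_from_reference",
    "mw_absolute",
    "porod_mw",
    "vc_mw",
    "load_porod_correction",
    "DEFAULT_QMAX_CUT",
    "DEFAULT_PROTEIN_DENSITY",
    "VC_CALIBRATION",
]

# Upper integration limit for the Porod/Vc integrals; common practice for
# folded macromolecules, clipped to the data range.
DEFAULT_QMAX_CUT = 0.3  # 1/A

# Protein packing density ~1.37 g/cm^3 expressed in kDa per cubic Angstrom.
DEFAULT_PROTEIN_DENSITY = 0.83e-3  # kDa / A^3

# Volume-of-correlation calibration (c, k): MW [Da] = (QR / c) ** k, with
# QR = Vc^2/Rg in A^3.  Conventional literature values for folded proteins
# and for RNA; user-overridable.  Results are reported in kDa.
VC_CALIBRATION = {
    "protein": (0.1231, 1.0),
    "rna": (0.00934, 0.808),
}


@dataclass
class ContrastParams:
    """Scattering contrast of a macromolecule in aqueous solvent.

    Defaults are the conventional values for proteins in water:
    3.22e23 electrons per gram of protein, solvent electron density
    3.34e23 e/cm^3, partial specific volume 0.7425 cm^3/g, and the Thomson
    scattering length 2.8179e-13 cm.
    """

    electrons_per_gram: float = 3.22e23
    solvent_electron_density: float = 3.34e23
    partial_specific_volume: float = 0.7425
    thomson_radius: float = 2.8179e-13

    def __post_init__(self) -> None:
        for name in ("electrons_per_gram", "solvent_electron_density",
                     "partial_specific_volume", "thomson_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"contrast parameter {name!r} must be > 0")

    def contrast_per_mass(self) -> float:
        """Delta-rho_M in cm/g: excess scattering length per unit mass."""
        return self.thomson_radius * (
            self.electrons_per_gram
            - self.solvent_electron_density * self.partial_specific_volume
        )


@dataclass
class MWResult:
    method: str
    mw: float  # kDa
    intermediates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _store(profile: ScatteringProfile | None, result: MWResult) -> MWResult:
    if profile is not None:
        profile.analysis.setdefault("molweight", {})[result.method] = result.to_dict()
    return result


def mw_from_reference(
    i0_sample: float,
    conc_sample: float,
    i0_ref: float,
    conc_ref: float,
    mw_ref: float,
    profile: ScatteringProfile | None = None,
) -> MWResult:
    """MW from the I(0)/c ratio against a standard of known MW (kDa).

    I(0) is proportional to c*MW, so
    MW = MW_ref * (I0_sample/c_sample) / (I0_ref/c_ref).
    """
    for name, v in (("i0_sample", i0_sample), ("conc_sample", conc_sample),
                    ("i0_ref", i0_ref), ("conc_ref", conc_ref),
                    ("mw_ref", mw_ref)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    mw = mw_ref * (i0_sample / conc_sample) / (i0_ref / conc_ref)
    return _store(profile, MWResult("reference", float(mw)))


def mw_absolute(
    i0_abs: float,
    conc: float,
    contrast: ContrastParams | None = None,
    profile: ScatteringProfile | None = None,
) -> MWResult:
    """MW from absolute-scale I(0) in 1/cm and concentration in mg/ml.

    MW [g/mol] = N_A * I(0) / (c * Delta-rho_M^2) with c in g/cm^3 and
    Delta-rho_M the contrast per unit mass; reported in kDa.
    """
    if i0_abs <= 0 or conc <= 0:
        raise ValueError("i0_abs and conc must be > 0")
    contrast = contrast or ContrastParams()
    drho = contrast.contrast_per_mass()
    c_g_cm3 = conc * 1e-3  # mg/ml -> g/cm^3
    mw_da = Avogadro * i0_abs / (c_g_cm3 * drho * drho)
    return _store(profile, MWResult(
        "absolute", float(mw_da / 1000.0),
        {"contrast_per_mass": drho},
    ))


def _guinier_extended_curve(
    profile: ScatteringProfile, guinier: GuinierResult, qmax_cut: float
) -> tuple[np.ndarray, np.ndarray]:
    """Measured curve truncated at qmax_cut, preceded by the Guinier model
    I0*exp(-q^2 Rg^2/3) on a grid from 0 to the first data point, spaced
    like the first data spacing."""
    if not guinier.valid or not np.isfinite(guinier.rg) or guinier.rg <= 0:
        raise ValueError("a valid Guinier result is required for the q=0 extrapolation")
    q = profile.q
    i = profile.intensity
    if qmax_cut > q[-1] + 1e-12:
        raise ValueError(f"qmax_cut {qmax_cut} beyond data range (max q {q[-1]})")
    keep = q <= qmax_cut
    q_data, i_data = q[keep], i[keep]
    dq = q[1] - q[0]
    q_ext = np.arange(0.0, q_data[0] - 1e-12 * max(dq, 1e-30), dq)
    i_ext = guinier.i0 * np.exp(-(q_ext**2) * guinier.rg**2 / 3.0)
    return np.concatenate([q_ext, q_data]), np.concatenate([i_ext, i_data])


def porod_invariant(q: np.ndarray, i: np.ndarray) -> float:
    """Q = integral q^2 I(q) dq by the trapezoid rule."""
    return float(np.trapezoid(q * q * i, q))


def load_porod_correction(path) -> list:
    """Load a Porod-volume correction table: a JSON list of
    [qmax, A, B] rows giving Vp_corrected = A + B*Vp, interpolated in qmax."""
    with open(str(path), "r", encoding="utf-8") as fh:
        table = json.load(fh)
    if not all(len(row) == 3 for row in table):
        raise ValueError("correction table rows must be [qmax, A, B]")
    return table


def _correction_at(table, qmax_cut: float) -> tuple[float, float]:
    if table is None:
        return 0.0, 1.0
    arr = np.asarray(sorted(table), dtype=float)
    a = float(np.interp(qmax_cut, arr[:, 0], arr[:, 1]))
    b = float(np.interp(qmax_cut, arr[:, 0], arr[:, 2]))
    return a, b


def porod_mw(
    profile: ScatteringProfile,
    guinier: GuinierResult,
    qmax_cut: float | None = None,
    correction=None,
    density: float = DEFAULT_PROTEIN_DENSITY,
    store: bool = True,
) -> MWResult:
    """MW from the Porod volume with an optional linear truncation correction.

    The Porod invariant Q = integral q^2 I dq is evaluated over the
    Guinier-extended curve up to `qmax_cut`; Vp = 2*pi^2*I(0)/Q; the
    correction table (rows [qmax, A, B]) maps Vp -> A + B*Vp, compensating
    the finite upper integration limit; default is the identity.  MW is
    density * Vp_corrected with density in kDa/A^3.
    """
    qmax_cut = min(DEFAULT_QMAX_CUT, profile.q[-1]) if qmax_cut is None else qmax_cut
    if guinier.valid and qmax_cut < profile.q[min(guinier.idx_max, len(profile) - 1)]:
        raise ValueError("qmax_cut lies below the end of the Guinier region")
    qc, ic = _guinier_extended_curve(profile, guinier, qmax_cut)
    q_inv = porod_invariant(qc, ic)
    vp = 2.0 * np.pi**2 * guinier.i0 / q_inv
    a, b = _correction_at(correction, qmax_cut)
    vp_corr = a + b * vp
    result = MWResult(
        "porod", float(density * vp_corr),
        {"q_inv": float(q_inv), "vp": float(vp), "vp_corrected": float(vp_corr),
         "qmax_cut": float(qmax_cut)},
    )
    return _store(profile if store else None, result)


def vc_mw(
    profile: ScatteringProfile,
    guinier: GuinierResult,
    qmax_cut: float | None = None,
    molecule: str = "protein",
    calibration: tuple[float, float] | None = None,
    store: bool = True,
) -> MWResult:
    """MW from the volume of correlation; concentration-independent.

    Vc = I(0) / integral_0^qmax q*I(q) dq over the Guinier-extended curve;
    QR = Vc^2 / Rg; MW = (QR / c) ** k in Da with (c, k) chosen per molecule
    class ("protein" or "rna") or supplied explicitly; reported in kDa.
    """
    if not guinier.valid:
        raise ValueError("vc_mw requires a valid Guinier result")
    qmax_cut = min(DEFAULT_QMAX_CUT, profile.q[-1]) if qmax_cut is None else qmax_cut
    qc, ic = _guinier_extended_curve(profile, guinier, qmax_cut)
    integral = float(np.trapezoid(qc * ic, qc))
    vc = guinier.i0 / integral
    qr = vc * vc / guinier.rg
    if calibration is None:
        if molecule not in VC_CALIBRATION:
            raise ValueError(f"unknown molecule class {molecule!r}")
        calibration = VC_CALIBRATION[molecule]
    c, k = calibration
    mw_da = (qr / c) ** k
    result = MWResult(
        "vc", float(mw_da / 1000.0),
        {"vc": float(vc), "qr": float(qr), "qmax_cut": float(qmax_cut),
         "molecule": molecule},
    )
    return _store(profile if store else None, result)
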
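"""Fluorescence calibration and absolute enzyme quantification.

Calibration is an ordinary least-squares line intensity = slope*conc +
intercept fitted to labeled-enzyme standards; inverse prediction converts a
stripped-electrode reading to a molar concentration, Avogadro scaling to an
absolute enzyme count, and the nanoparticle estimate to enzymes per particle
and per-enzyme footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import constants as _const
from scipy import stats

from .nanoparticle_model import NM2_PER_CM2, NPEstimate, hemisphere_area

__all__ = [
    "CalibrationCurve",
    "ConcentrationResult",
    "EnzymeReport",
    "CalibrationError",
    "fit_calibration",
    "concentration_from_intensity",
    "enzyme_count",
    "per_np_and_footprint",
    "degree_of_labeling",
    "DEFAULT_STRIP_VOLUME_L",
]

#: Default stripping-solution volume the electrode tip is immersed in (200 uL).
DEFAULT_STRIP_VOLUME_L = 200e-6


class CalibrationError(ValueError):
    """Raised for unusable or unfittable calibration data."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-vs-concentration model with fit diagnostics."""

    slope: float  # intensity per (mol/L)
    intercept: float  # intensity
    r2: float
    n_points: int
    conc_range: tuple[float, float]  # mol/L
    blank: float  # intensity at zero concentration (= intercept)
    usable: bool = True

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class ConcentrationResult:
    """Inverse-predicted concentration with quality flags."""

    conc: float  # mol/L, floored at 0
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EnzymeReport:
    """Absolute enzyme quantification for one electrode.

    ``count = conc * volume * N_A``; ``per_np = count / n_np``; ``footprint``
    is the NP surface area available per enzyme (nm^2), None when no enzymes
    were detected.
    """

    conc: float  # mol/L
    count: float  # enzymes
    per_np: float  # enzymes per nanoparticle
    footprint: float | None  # nm^2 per enzyme
    volume: float = DEFAULT_STRIP_VOLUME_L  # L
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("conc", "count", "per_np"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.volume > 0:
            raise ValueError("volume must be > 0")


def fit_calibration(standards: Iterable[tuple[float, float]]) -> CalibrationCurve:
    """OLS fit of intensity vs concentration for >= 3 distinct standards.

    A negative slope yields a curve flagged ``usable=False`` rather than an
    exception so the defect can be reported alongside the electrode.
    """
    pts = [(float(c), float(i)) for c, i in standards]
    if len(pts) < 3:
        raise CalibrationError(f"need >= 3 standards, got {len(pts)}")
    conc = np.array([p[0] for p in pts])
    inten = np.array([p[1] for p in pts])
    if np.unique(conc).size < 2:
        raise CalibrationError("all standards share one concentration; fit is rank-deficient")
    if np.unique(conc).size < 3:
        raise CalibrationError("need >= 3 distinct concentrations")
    fit = stats.linregress(conc, inten)
    usable = fit.slope > 0
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_points=len(pts),
        conc_range=(float(conc.min()), float(conc.max())),
        blank=float(fit.intercept),
        usable=usable,
    )


def concentration_from_intensity(curve: CalibrationCurve, intensity: float) -> ConcentrationResult:
    """Inverse prediction ``(intensity - intercept) / slope`` with flags.

    Negative results are floored at 0 (flag ``below_blank``); readings whose
    implied concentration falls outside the standards' range are flagged
    ``extrapolated``.
    """
    if not curve.usable:
        raise CalibrationError("calibration curve is flagged unusable (non-positive slope)")
    conc = (float(intensity) - curve.intercept) / curve.slope
    flags: list[str] = []
    if conc < 0:
        flags.append("below_blank")
        conc = 0.0
    lo, hi = curve.conc_range
    if conc < lo or conc > hi:
        flags.append("extrapolated")
    return ConcentrationResult(conc=conc, flags=tuple(flags))


def enzyme_count(conc: float, volume: float = DEFAULT_STRIP_VOLUME_L) -> float:
    """Absolute number of enzymes in ``volume`` litres at ``conc`` mol/L."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if not volume > 0:
        raise ValueError("volume must be > 0")
    return conc * volume * _const.N_A


def per_np_and_footprint(
    count: float,
    np_est: NPEstimate,
    conc: float | None = None,
    volume: float = DEFAULT_STRIP_VOLUME_L,
    flags: Sequence[str] = (),
) -> EnzymeReport:
    """Enzymes per NP and per-enzyme footprint from a count and NP estimate.

    The footprint is computed two ways — total NP area per enzyme
    ``s_total/count`` and per-particle area per enzyme
    ``hemisphere_area(d)/per_np`` — which must agree (< 0.1%) for the default
    hemisphere shape factor; disagreement is flagged, not hidden.
    """
    if not np_est.n_np > 0:
        raise ValueError("nanoparticle count must be > 0")
    if count < 0:
        raise ValueError("enzyme count must be >= 0")
    out_flags = list(flags)
    per_np = count / np_est.n_np
    if conc is None:
        conc = count / (volume * _const.N_A)
    if count == 0:
        return EnzymeReport(
            conc=conc, count=0.0, per_np=0.0, footprint=None,
            volume=volume, flags=tuple(out_flags + ["no_enzymes_detected"]),
        )
    s_nm2 = np_est.s_total * NM2_PER_CM2
    footprint = s_nm2 / count
    alt = hemisphere_area(np_est.d) / per_np
    if abs(footprint - alt) > 1e-3 * footprint:
        out_flags.append("footprint_routes_disagree")
    return EnzymeReport(
        conc=conc, count=count, per_np=per_np, footprint=footprint,
        volume=volume, flags=tuple(out_flags),
    )


def degree_of_labeling(
    a_dye: float,
    a_280: float,
    eps_dye: float,
    eps_protein: float,
    cf_280: float = 0.0,
) -> tuple[float, float]:
    """Fluorophores per protein and protein concentration from UV-Vis absorbances.

    ``protein_conc = (A280 - cf_280 * A_dye) / eps_protein`` corrects the
    280-nm absorbance for the dye's own contribution; the degree of labeling
    is ``A_dye / (eps_dye * protein_conc)``.  Extinction coefficients in
    L mol^-1 cm^-1 (1-cm path assumed).

    Returns ``(dol, protein_conc_mol_per_l)``.
    """
    if a_dye < 0 or a_280 < 0:
        raise ValueError("absorbances must be >= 0")
    if not (eps_dye > 0 and eps_protein > 0):
        raise ValueError("extinction coefficients must be > 0")
    corrected = a_280 - cf_280 * a_dye
    if not corrected > 0:
        raise ValueError(
            f"dye-corrected A280 = {corrected:.4g} <= 0: over-correction or no protein"
        )
    protein_conc = corrected / eps_protein
    dol = a_dye / (eps_dye * protein_conc)
    return dol, protein_conc
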
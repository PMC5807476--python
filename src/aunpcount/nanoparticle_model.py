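"""Charge-to-geometry conversions for hemispherical gold nanoparticles.

The anodic stripping charge of the whole NP population is

    q_strip = n_eff * e * ((x/3) * pi * r^3 * rho_Au / M_Au) * N_A * n_np

with r the ensemble mean radius (cm) and x the shape factor (2 for a
hemisphere).  The gold-oxide reduction charge gives the real gold surface
area ``s_total = q_ox / k_ox``, and ``s_total = x * pi * r^2 * n_np`` closes
the system: r follows from the charge ratio, n_np from the area.

All internal arithmetic is in CGS-consistent units (cm, g, C); radii cross
the API boundary in nm, areas in cm^2 (electrode scale) or nm^2 (particle
scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from scipy import constants as _const

logger = logging.getLogger(__name__)

__all__ = [
    "StrippingConstants",
    "NPEstimate",
    "K_OX_CHOICES",
    "DEFAULT_CONSTANTS",
    "area_from_oxide_charge",
    "radius_from_charges",
    "count_from_area",
    "stripping_charge_forward",
    "oxide_charge_forward",
    "coverage",
    "geometric_area_cm2",
    "hemisphere_area",
    "enzyme_packing",
    "estimate_np",
]

NM_PER_CM = 1e7
NM2_PER_CM2 = 1e14

#: Literature coulometric coefficients (C/cm^2) for reducing a monolayer of
#: gold surface oxide, selectable by the name of the proposing group.
K_OX_CHOICES: dict[str, float] = {
    "habrioux": 543e-6,
    "trasatti": 400e-6,
    "tan": 450e-6,
    "finot": 489e-6,
}
_K_OX_KNOWN = frozenset(K_OX_CHOICES.values())


@dataclass(frozen=True)
class StrippingConstants:
    """Physical constants and conventions of the charge-to-geometry model.

    Attributes
    ----------
    k_ox : float
        Coulometric coefficient, C per cm^2 of real gold surface.
    n_eff : float
        Mean electrons transferred per gold atom during stripping (the
        chloro-complex equilibria average close to 1.9).
    x : float
        Shape factor; 2 for hemispheres sitting flat on the electrode.
    e, n_a : float
        Elementary charge (C) and Avogadro's number (1/mol).
    rho_au, m_au : float
        Density (g/cm^3) and molar mass (g/mol) of gold.
    """

    k_ox: float = 489e-6
    n_eff: float = 1.9
    x: float = 2.0
    e: float = _const.e
    n_a: float = _const.N_A
    rho_au: float = 19.3
    m_au: float = 196.97

    def __post_init__(self) -> None:
        for name in ("k_ox", "n_eff", "x", "e", "n_a", "rho_au", "m_au"):
            if not getattr(self, name) > 0:
                raise ValueError(f"constant {name} must be strictly positive")
        if not any(math.isclose(self.k_ox, k, rel_tol=1e-9) for k in _K_OX_KNOWN):
            logger.warning(
                "k_ox=%.6g C/cm^2 is not one of the literature values %s",
                self.k_ox,
                sorted(_K_OX_KNOWN),
            )

    def with_k_ox(self, choice: str | float) -> "StrippingConstants":
        """Return a copy with ``k_ox`` selected by name or numeric value."""
        if isinstance(choice, str):
            key = choice.lower()
            if key in K_OX_CHOICES:
                return replace(self, k_ox=K_OX_CHOICES[key])
            # allow '489' / '543' style selection in uC/cm^2
            try:
                val = float(key) * 1e-6
            except ValueError:
                raise KeyError(f"unknown k_ox choice {choice!r}; known: {sorted(K_OX_CHOICES)}")
            return replace(self, k_ox=val)
        return replace(self, k_ox=float(choice))


DEFAULT_CONSTANTS = StrippingConstants()


@dataclass(frozen=True)
class NPEstimate:
    """Per-electrode nanoparticle ensemble estimate.

    ``s_total = x * pi * r^2 * n_np`` holds by construction (checked to
    relative 1e-10); ``coverage`` is the projected footprint area of the
    hemispheres as a percentage of the geometric disc area ``a_geom``.
    """

    r: float  # mean radius, nm
    n_np: float  # particle count (ensemble estimate, not rounded)
    s_total: float  # total real NP surface area, cm^2
    coverage: float  # % of geometric electrode area
    a_geom: float  # geometric electrode area, cm^2
    q_strip: float  # C, input echoed
    q_ox: float  # C, input echoed
    x: float = 2.0

    def __post_init__(self) -> None:
        for name in ("r", "n_np", "s_total", "coverage", "a_geom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        r_cm = self.r / NM_PER_CM
        s_check = self.x * math.pi * r_cm**2 * self.n_np
        if self.s_total > 0 and abs(s_check - self.s_total) > 1e-10 * self.s_total:
            raise ValueError("inconsistent estimate: s_total != x*pi*r^2*n_np")

    @property
    def d(self) -> float:
        """Mean diameter, nm."""
        return 2.0 * self.r


def area_from_oxide_charge(q_ox: float, c: StrippingConstants = DEFAULT_CONSTANTS) -> float:
    """Total real gold surface area (cm^2) from the oxide-reduction charge (C)."""
    if q_ox < 0:
        raise ValueError(f"oxide-reduction charge must be >= 0, got {q_ox}")
    return q_ox / c.k_ox


def radius_from_charges(
    q_strip: float, s_total: float, c: StrippingConstants = DEFAULT_CONSTANTS
) -> float:
    """Mean NP radius (nm) from the stripping charge (C) and real area (cm^2).

    ``r = 3 M_Au / (n_eff e rho_Au N_A) * q_strip / s_total``; independent of
    the shape factor x.
    """
    if not q_strip > 0:
        raise ValueError(f"stripping charge must be > 0, got {q_strip}")
    if not s_total > 0:
        raise ValueError(f"surface area must be > 0, got {s_total}")
    r_cm = (3.0 * c.m_au) / (c.n_eff * c.e * c.rho_au * c.n_a) * (q_strip / s_total)
    return r_cm * NM_PER_CM


def count_from_area(
    s_total: float, r: float, c: StrippingConstants = DEFAULT_CONSTANTS
) -> float:
    """Particle count from the real area (cm^2) and mean radius (nm).

    Returns the (non-integer) ensemble estimate ``s_total / (x pi r^2)``.
    """
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r}")
    if s_total < 0:
        raise ValueError(f"surface area must be >= 0, got {s_total}")
    r_cm = r / NM_PER_CM
    return s_total / (c.x * math.pi * r_cm**2)


def stripping_charge_forward(
    r: float, n_np: float, c: StrippingConstants = DEFAULT_CONSTANTS
) -> float:
    """Forward model: stripping charge (C) of n_np particles of radius r (nm)."""
    if r < 0 or n_np < 0:
        raise ValueError("radius and count must be >= 0")
    r_cm = r / NM_PER_CM
    atoms_per_np = (c.x / 3.0) * math.pi * r_cm**3 * c.rho_au / c.m_au * c.n_a
    return c.n_eff * c.e * atoms_per_np * n_np


def oxide_charge_forward(
    r: float, n_np: float, c: StrippingConstants = DEFAULT_CONSTANTS
) -> float:
    """Forward model: oxide-reduction charge (C) for the same ensemble."""
    if r < 0 or n_np < 0:
        raise ValueError("radius and count must be >= 0")
    r_cm = r / NM_PER_CM
    return c.k_ox * c.x * math.pi * r_cm**2 * n_np


def geometric_area_cm2(electrode_diameter_mm: float) -> float:
    """Geometric disc area (cm^2) of a working electrode of given diameter (mm)."""
    if not electrode_diameter_mm > 0:
        raise ValueError("electrode diameter must be > 0")
    r_cm = electrode_diameter_mm / 20.0  # mm diameter -> cm radius
    return math.pi * r_cm**2


def coverage(r: float, n_np: float, electrode_diameter_mm: float) -> float:
    """Projected NP coverage (%) of the geometric electrode disc.

    Uses the footprint ``pi r^2`` of each hemisphere; values above 100% are
    geometrically impossible for non-overlapping particles and are logged.
    """
    a_geom = geometric_area_cm2(electrode_diameter_mm)
    r_cm = r / NM_PER_CM
    cov = 100.0 * math.pi * r_cm**2 * n_np / a_geom
    if cov > 100.0:
        logger.warning("coverage %.1f%% exceeds 100%% — overlapping-particle regime", cov)
    return cov


def hemisphere_area(d: float) -> float:
    """Curved surface area (nm^2) of a hemisphere of diameter d (nm).

    The flat face contacts the electrode and is excluded: ``2 pi (d/2)^2``.
    """
    if d < 0:
        raise ValueError("diameter must be >= 0")
    return 2.0 * math.pi * (d / 2.0) ** 2


def enzyme_packing(area: float, footprint: float, mode: str = "round") -> int:
    """Maximum whole enzymes of a given footprint (nm^2) on an area (nm^2).

    ``mode='round'`` rounds area/footprint to the nearest integer,
    ``mode='floor'`` truncates; both conventions appear in close-packing
    estimates, so the choice is explicit.
    """
    if not footprint > 0:
        raise ValueError(f"footprint must be > 0, got {footprint}")
    if area < 0:
        raise ValueError("area must be >= 0")
    ratio = area / footprint
    if mode == "round":
        return int(math.floor(ratio + 0.5))
    if mode == "floor":
        return int(math.floor(ratio))
    raise ValueError(f"mode must be 'round' or 'floor', got {mode!r}")


def estimate_np(
    q_strip: float,
    q_ox: float,
    electrode_diameter_mm: float = 3.0,
    c: StrippingConstants = DEFAULT_CONSTANTS,
) -> NPEstimate:
    """Full per-electrode inversion: charges -> (r, n_np, s_total, coverage)."""
    s_total = area_from_oxide_charge(q_ox, c)
    r = radius_from_charges(q_strip, s_total, c)
    n_np = count_from_area(s_total, r, c)
    cov = coverage(r, n_np, electrode_diameter_mm)
    return NPEstimate(
        r=r,
        n_np=n_np,
        s_total=s_total,
        coverage=cov,
        a_geom=geometric_area_cm2(electrode_diameter_mm),
        q_strip=q_strip,
        q_ox=q_ox,
        x=c.x,
    )
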
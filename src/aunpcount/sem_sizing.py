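"""Size-distribution and coverage statistics from particle measurement tables.

Operates on tables exported by image-analysis software (one row per
segmented particle, equivalent-circle diameter or projected area); the
segmentation itself is out of scope.  The diameter distribution is fitted by
least squares with a Gaussian on the binned histogram — matching the usual
histogram-plus-fit presentation — and sample mean/SD are always reported
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ParticleTable",
    "DiameterFit",
    "fit_diameter_distribution",
    "coverage_from_table",
    "DEFAULT_BIN_WIDTH_NM",
    "MIN_PARTICLES_FOR_FIT",
]

DEFAULT_BIN_WIDTH_NM = 2.0
MIN_PARTICLES_FOR_FIT = 30


@dataclass(frozen=True)
class ParticleTable:
    """Per-particle diameters (nm) plus optional imaged-field provenance."""

    diameters: np.ndarray  # nm, all > 0
    field_area: float | None = None  # nm^2 of the imaged region(s)
    n_images: int = 1
    pixel_size: float | None = None  # nm/px, provenance only

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "diameters", d)
        if d.ndim != 1:
            raise ValueError("diameters must be 1-D")
        if d.size and not (d > 0).all():
            raise ValueError("all diameters must be > 0")
        if self.field_area is not None and not self.field_area > 0:
            raise ValueError("field_area must be > 0 when given")

    @classmethod
    def from_areas(cls, areas_nm2, **kwargs) -> "ParticleTable":
        """Build from projected particle areas via equivalent-circle diameter."""
        a = np.asarray(areas_nm2, dtype=float)
        if a.size and not (a > 0).all():
            raise ValueError("all areas must be > 0")
        return cls(diameters=2.0 * np.sqrt(a / math.pi), **kwargs)

    @classmethod
    def read_table(cls, path: str | Path, **kwargs) -> "ParticleTable":
        """Read a delimited table with a ``diameter_nm`` or ``area_nm2`` column."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        cols = {c.strip().lower(): c for c in df.columns}
        if "diameter_nm" in cols:
            return cls(diameters=df[cols["diameter_nm"]].to_numpy(float), **kwargs)
        if "area_nm2" in cols:
            return cls.from_areas(df[cols["area_nm2"]].to_numpy(float), **kwargs)
        raise ValueError(f"{path}: expected a 'diameter_nm' or 'area_nm2' column, got {list(df.columns)}")

    def __len__(self) -> int:
        return int(self.diameters.size)


@dataclass(frozen=True)
class DiameterFit:
    """Histogram Gaussian fit plus direct sample statistics."""

    mu: float | None  # nm, fitted Gaussian centre (None if fit skipped)
    sigma: float | None  # nm
    adj_r2: float | None
    sample_mean: float
    sample_sd: float
    n: int
    n_bins: int
    bin_width: float
    fitted: bool
    notice: str | None = None


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_diameter_distribution(
    t: ParticleTable, bin_width: float = DEFAULT_BIN_WIDTH_NM
) -> DiameterFit:
    """Histogram the diameters and fit a Gaussian to the bin counts.

    Adjusted R^2 uses 3 fitted parameters:
    ``1 - (1 - R^2) (n_bins - 1) / (n_bins - 4)``.  With fewer than
    ``MIN_PARTICLES_FOR_FIT`` particles (or a degenerate sample) the fit is
    skipped and only sample statistics are returned.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    d = t.diameters
    n = d.size
    if n == 0:
        raise ValueError("empty particle table")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if n > 1 else 0.0

    def skipped(msg: str, n_bins: int = 0) -> DiameterFit:
        return DiameterFit(None, None, None, mean, sd, n, n_bins, bin_width, False, msg)

    if n < MIN_PARTICLES_FOR_FIT:
        return skipped(f"only {n} particles (< {MIN_PARTICLES_FOR_FIT}); Gaussian fit skipped")
    if sd == 0.0:
        return skipped("degenerate sample (all diameters identical); Gaussian fit refused")

    lo = bin_width * math.floor(d.min() / bin_width)
    hi = bin_width * math.ceil(d.max() / bin_width)
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = counts.size
    if n_bins < 5:
        return skipped(f"only {n_bins} bins at width {bin_width} nm; fit under-determined", n_bins)
    assert counts.sum() == n

    p0 = (float(counts.max()), mean, sd)
    try:
        popt, _ = curve_fit(_gauss, centers, counts.astype(float), p0=p0, maxfev=10000)
    except RuntimeError as exc:
        return skipped(f"Gaussian fit did not converge: {exc}", n_bins)
    a_fit, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    resid = counts - _gauss(centers, a_fit, mu, sigma)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n_bins - 1) / (n_bins - 4)
    return DiameterFit(mu, sigma, adj_r2, mean, sd, n, n_bins, bin_width, True, None)


def coverage_from_table(t: ParticleTable) -> float:
    """Projected particle coverage (%) of the imaged field.

    ``100 * sum(pi (d_i/2)^2) / field_area``.
    """
    if t.field_area is None:
        raise ValueError("field_area is required to compute coverage")
    if len(t) == 0:
        return 0.0
    proj = math.pi * np.sum((t.diameters / 2.0) ** 2)
    return float(100.0 * proj / t.field_area)
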
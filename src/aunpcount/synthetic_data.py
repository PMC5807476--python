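"""Forward simulation of every raw input the analysis pipeline consumes.

From a per-electrode ground truth (diameter distribution, particle count,
enzyme surface density, noise levels) this module generates:

* an oxide-reduction linear sweep (+1.7 -> +0.8 V) whose faradaic charge is
  ``k_ox * S`` with ``S`` the summed curved surface area of the particles,
* a 6-cycle stripping voltammogram (+0.9 <-> +1.5 V) whose faradaic charge
  is the per-particle gold content summed over the population (>= 99% of it
  placed in cycle 1),
* fluorescence standards and a stripped-electrode sample reading from a
  linear intensity model.

The generator keeps its own per-particle bookkeeping (sums of d^2 and d^3
over the drawn population) and never calls the estimator's closed-form
inversions, so mean-field bias of the mean-radius method under
polydispersity is measurable instead of hidden.  Peak shapes are
phenomenological Gaussians on a capacitive (linear + mild quadratic)
baseline; electrode kinetics are out of scope.

Very large populations are represented by a capped random subsample with a
per-particle weight ``n_np / n_drawn``; moments are unbiased.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nanoparticle_model import DEFAULT_CONSTANTS, NM_PER_CM, NM2_PER_CM2, StrippingConstants
from .voltammetry_io import Voltammogram, write_voltammogram

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "Population",
    "generate_ensemble",
    "draw_population",
    "simulate_voltammograms",
    "simulate_fluorescence",
    "simulate_electrode",
    "write_electrode_files",
    "MAX_PARTICLE_DRAWS",
]

MAX_PARTICLE_DRAWS = 100_000

E_STEP_V = 1e-3  # sampling interval of all simulated sweeps
SCAN_RATE_V_S = 0.1
OXIDE_E_START, OXIDE_E_END = 1.7, 0.8  # downward linear sweep
STRIP_E_LOW, STRIP_E_HIGH = 0.9, 1.5  # triangular cycles
N_STRIP_CYCLES = 6
OXIDE_PEAK_E, OXIDE_PEAK_SIGMA = 1.1, 0.040  # V
STRIP_PEAK_E, STRIP_PEAK_SIGMA = 1.3, 0.035  # V
STRIP_CYCLE1_FRACTION = 0.995  # remainder goes to cycle 2


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument imperfections added to simulated raw data."""

    current_rms_a: float = 2e-7  # white current noise, A RMS
    baseline_a: float = 2e-6  # capacitive baseline magnitude, A
    baseline_slope_a_per_v: float = 5e-6
    baseline_curv_a_per_v2: float = 2e-6
    fluorescence_cv: float = 0.02  # multiplicative CV on intensities

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one electrode; every output is reproducible from it."""

    d_mean: float  # nm
    d_sd: float  # nm
    n_np: float  # particles on the electrode
    enzyme_density: float = 0.0  # enzymes per nm^2 of NP surface
    electrode_diameter_mm: float = 3.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.d_mean > 0:
            raise ValueError("d_mean must be > 0")
        if self.d_sd < 0 or self.n_np < 0 or self.enzyme_density < 0:
            raise ValueError("d_sd, n_np and enzyme_density must be >= 0")
        if not self.electrode_diameter_mm > 0:
            raise ValueError("electrode_diameter_mm must be > 0")


@dataclass(frozen=True)
class Population:
    """A drawn particle population with its exact generator bookkeeping."""

    diameters: np.ndarray  # nm, subsample of size <= MAX_PARTICLE_DRAWS
    weight: float  # particles represented by each drawn one
    n_np: float
    s_nm2: float  # weighted sum of curved (hemisphere) surface areas
    q_strip: float  # C, weighted per-particle gold content
    q_ox: float  # C, k_ox * total area

    @property
    def s_cm2(self) -> float:
        return self.s_nm2 / NM2_PER_CM2

    @property
    def d_charge_weighted(self) -> float:
        """sum(d^3)/sum(d^2): the diameter the mean-radius inversion targets."""
        d = self.diameters
        if d.size == 0:
            return float("nan")
        return float(np.sum(d**3) / np.sum(d**2))


def generate_ensemble(base: GroundTruth, n_electrodes: int) -> list[GroundTruth]:
    """Replicate a ground truth over electrodes with per-electrode seeds."""
    if n_electrodes < 0:
        raise ValueError("n_electrodes must be >= 0")
    return [replace(base, seed=base.seed + k) for k in range(n_electrodes)]


def _rng(gt: GroundTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(gt.seed) & 0x7FFFFFFF, stream])


def draw_population(
    gt: GroundTruth,
    c: StrippingConstants = DEFAULT_CONSTANTS,
    max_draw: int = MAX_PARTICLE_DRAWS,
) -> Population:
    """Draw the particle diameters and accumulate the generator's own sums.

    Diameters are Normal(d_mean, d_sd) truncated to > 0 by redraw.  The
    stripping charge is the weighted sum of per-particle gold content
    (hemisphere volume * rho/M * N_A atoms, n_eff electrons each); the oxide
    charge is ``k_ox`` times the weighted sum of curved surface areas.
    """
    rng = _rng(gt, 17)
    n_total = float(gt.n_np)
    n_draw = int(min(round(n_total), max_draw))
    if n_draw == 0:
        return Population(np.empty(0), 0.0, 0.0, 0.0, 0.0, 0.0)
    if gt.d_sd == 0:
        d = np.full(n_draw, float(gt.d_mean))
    else:
        d = rng.normal(gt.d_mean, gt.d_sd, size=n_draw)
        bad = d <= 0
        while bad.any():
            d[bad] = rng.normal(gt.d_mean, gt.d_sd, size=int(bad.sum()))
            bad = d <= 0
    weight = n_total / n_draw
    r_cm = (d / 2.0) / NM_PER_CM
    s_nm2 = weight * float(np.sum(2.0 * math.pi * (d / 2.0) ** 2))
    vol_cm3 = (c.x / 3.0) * math.pi * r_cm**3
    moles = vol_cm3 * c.rho_au / c.m_au
    q_strip = c.n_eff * c.e * c.n_a * weight * float(np.sum(moles))
    q_ox = c.k_ox * (s_nm2 / NM2_PER_CM2)
    return Population(d, weight, n_total, s_nm2, q_strip, q_ox)


def _gaussian_peak_current(e: np.ndarray, q: float, e0: float, sigma: float, nu: float) -> np.ndarray:
    """Current carrying total charge q shaped as a Gaussian in potential."""
    amp = q * nu / (sigma * math.sqrt(2.0 * math.pi))
    return amp * np.exp(-((e - e0) ** 2) / (2.0 * sigma**2))


def _capacitive(e: np.ndarray, direction: np.ndarray, ns: NoiseSpec, e_ref: float) -> np.ndarray:
    de = e - e_ref
    mag = ns.baseline_a + ns.baseline_slope_a_per_v * de + ns.baseline_curv_a_per_v2 * de**2
    return direction * mag


def simulate_voltammograms(
    gt: GroundTruth,
    c: StrippingConstants = DEFAULT_CONSTANTS,
    pop: Population | None = None,
) -> tuple[Voltammogram, Voltammogram]:
    """Simulate the oxide-reduction sweep and the 6-cycle stripping sweep.

    Returns ``(oxide_sweep, stripping_sweep)``, both vs NHE at 0.1 V/s and
    1 mV sampling, anodic-positive current.
    """
    if pop is None:
        pop = draw_population(gt, c)
    ns = gt.noise

    # --- oxide-reduction linear sweep (cathodic: current negative) ---
    n_ox = int(round((OXIDE_E_START - OXIDE_E_END) / E_STEP_V)) + 1
    e_ox = np.linspace(OXIDE_E_START, OXIDE_E_END, n_ox)
    i_ox = -_gaussian_peak_current(e_ox, pop.q_ox, OXIDE_PEAK_E, OXIDE_PEAK_SIGMA, SCAN_RATE_V_S)
    i_ox += _capacitive(e_ox, np.full_like(e_ox, -1.0), ns, OXIDE_E_END)
    rng_ox = _rng(gt, 1)
    if ns.current_rms_a > 0:
        i_ox += rng_ox.normal(0.0, ns.current_rms_a, size=e_ox.size)
    ox = Voltammogram(
        potential=e_ox, current=i_ox, scan_rate=SCAN_RATE_V_S,
        cycles=((0, e_ox.size),), reference="NHE", offset_to_nhe=0.0,
        meta={"kind": "oxide_reduction", "seed": str(gt.seed)},
    )

    # --- stripping cyclic voltammogram ---
    n_half = int(round((STRIP_E_HIGH - STRIP_E_LOW) / E_STEP_V)) + 1
    up = np.linspace(STRIP_E_LOW, STRIP_E_HIGH, n_half)
    down = np.linspace(STRIP_E_HIGH, STRIP_E_LOW, n_half)[1:]
    cycle_e = np.concatenate([up, down])  # 1201 samples, ends at E_LOW
    n_cyc = cycle_e.size
    fractions = [STRIP_CYCLE1_FRACTION, 1.0 - STRIP_CYCLE1_FRACTION] + [0.0] * (N_STRIP_CYCLES - 2)
    e_parts, i_parts, cycles = [], [], []
    rng_strip = _rng(gt, 2)
    for k in range(N_STRIP_CYCLES):
        direction = np.concatenate([np.ones(up.size), -np.ones(down.size)])
        i_k = _capacitive(cycle_e, direction, ns, STRIP_E_LOW)
        i_far = _gaussian_peak_current(
            cycle_e, fractions[k] * pop.q_strip, STRIP_PEAK_E, STRIP_PEAK_SIGMA, SCAN_RATE_V_S
        )
        i_k = i_k + np.where(direction > 0, i_far, 0.0)  # stripping on anodic sweep only
        if ns.current_rms_a > 0:
            i_k += rng_strip.normal(0.0, ns.current_rms_a, size=n_cyc)
        e_parts.append(cycle_e)
        i_parts.append(i_k)
        cycles.append((k * n_cyc, (k + 1) * n_cyc))
    strip = Voltammogram(
        potential=np.concatenate(e_parts), current=np.concatenate(i_parts),
        scan_rate=SCAN_RATE_V_S, cycles=tuple(cycles), reference="NHE",
        offset_to_nhe=0.0, meta={"kind": "stripping", "seed": str(gt.seed)},
    )
    return ox, strip


@dataclass(frozen=True)
class FluorescenceSim:
    """Simulated fluorimetry inputs plus the planted truth."""

    standards: pd.DataFrame  # columns: id, conc_mol_per_l, intensity
    sample_intensity: float
    volume_l: float
    count_true: float
    conc_true: float


def simulate_fluorescence(
    gt: GroundTruth,
    cal_slope: float = 1e12,
    cal_intercept: float = 5.0,
    volume_l: float = 200e-6,
    n_standards: int = 6,
    c: StrippingConstants = DEFAULT_CONSTANTS,
    pop: Population | None = None,
) -> FluorescenceSim:
    """Simulate calibration standards and the stripped-electrode reading.

    The true enzyme count is ``enzyme_density * S`` (S in nm^2); intensities
    follow ``slope * conc + intercept`` with multiplicative noise of the
    configured CV.  Standards span the sample concentration with at least 5
    points (a fixed positive range when the sample is blank).
    """
    if n_standards < 5:
        raise ValueError("need >= 5 standards to span the sample")
    if pop is None:
        pop = draw_population(gt, c)
    rng = _rng(gt, 3)
    count_true = gt.enzyme_density * pop.s_nm2
    from scipy.constants import N_A  # local to keep module deps light

    conc_true = count_true / (N_A * volume_l)
    span_top = 2.5 * conc_true if conc_true > 0 else 1e-10
    concs = np.linspace(span_top / n_standards, span_top, n_standards)
    noise_std = rng.normal(0.0, 1.0, size=n_standards) if gt.noise.fluorescence_cv > 0 else np.zeros(n_standards)
    intensities = (cal_slope * concs + cal_intercept) * (1.0 + gt.noise.fluorescence_cv * noise_std)
    standards = pd.DataFrame(
        {
            "id": [f"std{k + 1}" for k in range(n_standards)],
            "conc_mol_per_l": concs,
            "intensity": intensities,
        }
    )
    eps = rng.normal(0.0, 1.0) if gt.noise.fluorescence_cv > 0 else 0.0
    sample_intensity = (cal_slope * conc_true + cal_intercept) * (1.0 + gt.noise.fluorescence_cv * eps)
    return FluorescenceSim(standards, float(sample_intensity), volume_l, count_true, conc_true)


@dataclass(frozen=True)
class ElectrodeSim:
    """Everything the pipeline needs for one electrode, plus the truth."""

    gt: GroundTruth
    population: Population
    oxide: Voltammogram
    stripping: Voltammogram
    fluorescence: FluorescenceSim

    @property
    def truth(self) -> dict:
        pop = self.population
        return {
            "d_mean": self.gt.d_mean,
            "d_sd": self.gt.d_sd,
            "d_charge_weighted": pop.d_charge_weighted,
            "n_np": pop.n_np,
            "s_cm2": pop.s_cm2,
            "q_strip": pop.q_strip,
            "q_ox": pop.q_ox,
            "enzyme_count": self.fluorescence.count_true,
            "per_np": (self.fluorescence.count_true / pop.n_np) if pop.n_np > 0 else 0.0,
            "electrode_diameter_mm": self.gt.electrode_diameter_mm,
            "seed": self.gt.seed,
        }


def simulate_electrode(
    gt: GroundTruth,
    cal_slope: float = 1e12,
    cal_intercept: float = 5.0,
    volume_l: float = 200e-6,
    c: StrippingConstants = DEFAULT_CONSTANTS,
) -> ElectrodeSim:
    """Simulate all raw inputs for one electrode from a shared population."""
    pop = draw_population(gt, c)
    ox, strip = simulate_voltammograms(gt, c, pop=pop)
    fluo = simulate_fluorescence(gt, cal_slope, cal_intercept, volume_l, c=c, pop=pop)
    return ElectrodeSim(gt, pop, ox, strip, fluo)


def write_electrode_files(sim: ElectrodeSim, outdir: str | Path, electrode_id: str) -> dict:
    """Write the simulated raw files for one electrode; return a manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ox_path = outdir / f"{electrode_id}_oxide.csv"
    strip_path = outdir / f"{electrode_id}_strip.csv"
    std_path = outdir / f"{electrode_id}_standards.csv"
    sample_path = outdir / f"{electrode_id}_sample.csv"
    write_voltammogram(sim.oxide, ox_path)
    write_voltammogram(sim.stripping, strip_path)
    sim.fluorescence.standards.to_csv(std_path, index=False)
    pd.DataFrame(
        {
            "electrode_id": [electrode_id],
            "intensity": [sim.fluorescence.sample_intensity],
            "volume_ul": [sim.fluorescence.volume_l * 1e6],
        }
    ).to_csv(sample_path, index=False)
    return {
        "electrode_id": electrode_id,
        "oxide": ox_path.name,
        "stripping": strip_path.name,
        "standards": std_path.name,
        "sample": sample_path.name,
        "electrode_diameter_mm": sim.gt.electrode_diameter_mm,
        "truth": sim.truth,
    }


def write_manifest(entries: list[dict], outdir: str | Path, seed: int) -> Path:
    """Write the electrode -> files/truth manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps({"seed": seed, "electrodes": entries}, indent=2) + "\n")
    return path
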
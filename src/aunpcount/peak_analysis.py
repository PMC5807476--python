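"""Baseline correction and charge integration of voltammetric peaks.

Charges are computed per cycle as ``q = (1/nu) * integral |i_corr(E)| dE``
(trapezoidal rule) over a potential window, restricted to samples swept in
the window's stated direction so that the return sweep of a cyclic
voltammogram cannot cancel or double-count the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .voltammetry_io import Voltammogram, detect_cycles

__all__ = [
    "PeakWindow",
    "BaselineRecord",
    "CorrectedSegment",
    "ChargeResult",
    "WindowRangeError",
    "ResolutionError",
    "subtract_baseline",
    "integrate_charge",
    "OXIDE_REDUCTION_WINDOW",
    "STRIPPING_WINDOW",
]

N_ANCHOR = 5  # samples pooled (median) at each window edge for the baseline


class WindowRangeError(ValueError):
    """Peak window lies (partly) outside the sweep's potential range."""


class ResolutionError(ValueError):
    """Too few samples inside the window for baseline anchoring."""


@dataclass(frozen=True)
class PeakWindow:
    """A potential window [e_start, e_end] vs NHE with a sweep direction.

    ``direction`` selects which sweep segments contribute: ``anodic`` means
    potential increasing (oxidation peaks), ``cathodic`` decreasing.
    ``cycles`` is ``"all"`` or an iterable of cycle indices.
    """

    e_start: float
    e_end: float
    direction: Literal["anodic", "cathodic"] = "anodic"
    cycles: object = "all"

    def __post_init__(self) -> None:
        if not self.e_end > self.e_start:
            raise ValueError(f"window width must be > 0 (got [{self.e_start}, {self.e_end}])")
        if self.direction not in ("anodic", "cathodic"):
            raise ValueError(f"direction must be anodic or cathodic, got {self.direction!r}")
        if self.cycles != "all":
            object.__setattr__(self, "cycles", tuple(sorted(set(int(k) for k in self.cycles))))

    def selected_cycles(self, v: Voltammogram) -> tuple[int, ...]:
        if self.cycles == "all":
            return tuple(range(v.n_cycles))
        bad = [k for k in self.cycles if not 0 <= k < v.n_cycles]
        if bad:
            raise ValueError(f"cycle indices {bad} out of range for {v.n_cycles} cycles")
        return self.cycles  # type: ignore[return-value]


# Defaults bracketing the gold-oxide reduction (~+1.1 V) and gold stripping
# (~+1.3 V) peaks, both vs NHE; override per analysis as needed.
OXIDE_REDUCTION_WINDOW = PeakWindow(0.90, 1.35, direction="cathodic")
STRIPPING_WINDOW = PeakWindow(1.10, 1.50, direction="anodic")


@dataclass(frozen=True)
class BaselineRecord:
    """Provenance of a subtracted baseline within one cycle."""

    method: str
    cycle: int
    anchor_low: tuple[float, float] | None  # (E, i) at the low-potential edge
    anchor_high: tuple[float, float] | None


@dataclass(frozen=True)
class CorrectedSegment:
    """Baseline-corrected samples of one cycle inside the window (sweep order)."""

    cycle: int
    potential: np.ndarray
    current: np.ndarray  # corrected current
    baseline: BaselineRecord


@dataclass(frozen=True)
class ChargeResult:
    """Integrated faradaic charge of a peak window.

    ``q`` (coulombs, >= 0) is the sum of ``per_cycle``; ``e_peak`` is the
    potential of the corrected-current extremum inside the window.
    """

    q: float
    e_peak: float
    per_cycle: tuple[float, ...]
    cycle_indices: tuple[int, ...]
    baselines: tuple[BaselineRecord, ...]
    window: PeakWindow
    method: str

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("charge must be non-negative")
        if abs(self.q - sum(self.per_cycle)) > 1e-12 * max(1.0, abs(self.q)):
            raise ValueError("q must equal the sum of per-cycle charges")


def _directional_samples(
    e: np.ndarray, i: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of one cycle belonging to segments swept in ``direction``."""
    want = 1 if direction == "anodic" else -1
    segs = detect_cycles(e) if e.size >= 2 else [(0, e.size)]
    # detect_cycles pairs segments; we need raw monotone runs here instead
    keep = np.zeros(e.size, dtype=bool)
    d = np.sign(np.diff(e))
    # a sample belongs to the direction of the step that leads away from it;
    # the final sample inherits the last step's direction
    step_dir = np.concatenate([d, d[-1:]]) if d.size else np.zeros(1)
    # fill zero steps with the previous nonzero direction
    last = 0.0
    for j in range(step_dir.size):
        if step_dir[j] == 0:
            step_dir[j] = last
        else:
            last = step_dir[j]
    keep = step_dir == want
    return e[keep], i[keep]


def subtract_baseline(
    v: Voltammogram,
    w: PeakWindow,
    method: Literal["linear_anchors", "flat"] = "linear_anchors",
) -> list[CorrectedSegment]:
    """Subtract a per-cycle baseline from the current inside the window.

    ``linear_anchors`` draws a straight line between anchor points, each the
    (median E, median i) of the ``N_ANCHOR`` samples nearest the window edge;
    ``flat`` subtracts nothing (zero baseline).  The anchors are recorded for
    provenance.
    """
    if method not in ("linear_anchors", "flat"):
        raise ValueError(f"unknown baseline method {method!r}")
    e_all = v.potential
    lo, hi = float(e_all.min()), float(e_all.max())
    tol = 1e-9
    if w.e_start < lo - tol or w.e_end > hi + tol:
        raise WindowRangeError(
            f"window [{w.e_start}, {w.e_end}] V outside sweep range [{lo}, {hi}] V"
        )
    out: list[CorrectedSegment] = []
    for k in w.selected_cycles(v):
        ec, ic = v.cycle(k)
        ed, idir = _directional_samples(ec, ic, w.direction)
        mask = (ed >= w.e_start - tol) & (ed <= w.e_end + tol)
        ew, iw = ed[mask], idir[mask]
        if ew.size < N_ANCHOR:
            raise ResolutionError(
                f"cycle {k}: only {ew.size} sample(s) inside window; need >= {N_ANCHOR}"
            )
        if method == "flat":
            rec = BaselineRecord("flat", k, None, None)
            out.append(CorrectedSegment(k, ew, iw.copy(), rec))
            continue
        order = np.argsort(ew)
        lo_idx = order[:N_ANCHOR]
        hi_idx = order[-N_ANCHOR:]
        e0, i0 = float(np.median(ew[lo_idx])), float(np.median(iw[lo_idx]))
        e1, i1 = float(np.median(ew[hi_idx])), float(np.median(iw[hi_idx]))
        if e1 == e0:
            baseline = np.full_like(iw, 0.5 * (i0 + i1))
        else:
            baseline = i0 + (i1 - i0) * (ew - e0) / (e1 - e0)
        rec = BaselineRecord("linear_anchors", k, (e0, i0), (e1, i1))
        out.append(CorrectedSegment(k, ew, iw - baseline, rec))
    return out


def integrate_charge(
    v: Voltammogram,
    w: PeakWindow,
    method: Literal["linear_anchors", "flat"] = "linear_anchors",
) -> ChargeResult:
    """Integrate the baseline-corrected peak to a charge.

    Per cycle, ``q_cycle = (1/nu) * trapz(|i_corr|, E)`` over the window
    restricted to the window's sweep direction; the total is the sum over the
    selected cycles.
    """
    if not v.scan_rate > 0:
        raise ValueError("scan rate must be > 0")
    segments = subtract_baseline(v, w, method)
    per_cycle: list[float] = []
    best = (-np.inf, np.nan)  # (|i|, E) of global extremum
    for seg in segments:
        order = np.argsort(seg.potential)
        e_sorted = seg.potential[order]
        i_sorted = np.abs(seg.current[order])
        q_k = float(np.trapezoid(i_sorted, e_sorted)) / v.scan_rate
        per_cycle.append(q_k)
        j = int(np.argmax(i_sorted))
        if i_sorted[j] > best[0]:
            best = (float(i_sorted[j]), float(e_sorted[j]))
    return ChargeResult(
        q=float(sum(per_cycle)),
        e_peak=best[1],
        per_cycle=tuple(per_cycle),
        cycle_indices=tuple(seg.cycle for seg in segments),
        baselines=tuple(seg.baseline for seg in segments),
        window=w,
        method=method,
    )
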
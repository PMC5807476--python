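"""Read, validate, convert and write voltammogram traces.

A :class:`Voltammogram` is an ordered potential/current sweep recorded at a
fixed scan rate against a named reference electrode.  Multi-cycle sweeps are
segmented into cycles at potential-direction reversals; each cycle is either
a single monotone ramp or one triangular excursion (up+down or down+up).

File formats
------------
``two_column_csv``
    Delimited text with two numeric columns (potential in V, current in A).
    Lines starting with ``#`` are treated as an optional ``# key = value``
    header.  Delimiter is auto-detected among comma / tab / semicolon /
    whitespace.
``instrument_text``
    A block of bare ``key=value`` lines followed by the numeric data block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Voltammogram",
    "VoltammogramFormatError",
    "ReferenceError_",
    "REFERENCE_OFFSETS_V",
    "detect_cycles",
    "read_voltammogram",
    "write_voltammogram",
    "to_nhe",
]

#: Default reference-electrode offsets to NHE, volts.  These are the usual
#: textbook values at 25 degC (Ag/AgCl in saturated KCl: +0.197 V;
#: Cu/CuSO4 saturated: +0.316 V); they are configuration defaults, not
#: measurements, and can be overridden per file or per call.
REFERENCE_OFFSETS_V: dict[str, float] = {
    "NHE": 0.0,
    "AgAgCl_sat": 0.197,
    "CuCuSO4": 0.316,
}

#: References that require a user-supplied calibration offset.
CALIBRATED_REFERENCES = frozenset({"AgWire_calibrated"})

KNOWN_REFERENCES = frozenset(REFERENCE_OFFSETS_V) | CALIBRATED_REFERENCES


class VoltammogramFormatError(ValueError):
    """Raised when a voltammogram file cannot be parsed."""


class ReferenceError_(ValueError):
    """Raised when a reference electrode has no usable offset to NHE."""


def detect_cycles(potential: Sequence[float], hysteresis: int = 3) -> list[tuple[int, int]]:
    """Segment a potential trace into cycles at direction reversals.

    A reversal is only accepted when the new direction persists for at least
    ``hysteresis`` consecutive samples (tolerates ADC jitter).  Monotone
    segments are then paired: an up segment followed by a down segment (or
    vice versa) forms one triangular cycle; a trailing unpaired segment is a
    cycle of its own.

    Returns a list of half-open index ranges ``(start, stop)`` covering the
    trace; consecutive cycles share their apex sample boundary.
    """
    e = np.asarray(potential, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("potential must be a 1-D array with at least 2 samples")
    d = np.sign(np.diff(e))

    # Monotone segment boundaries (indices into e where direction flips).
    boundaries: list[int] = [0]
    directions: list[int] = []
    cur = 0
    run_sign = 0
    run_len = 0
    run_start = 0
    for j, s in enumerate(d):
        if s == 0:
            continue
        if cur == 0:
            cur = int(s)
            continue
        if s == cur:
            run_sign = 0
            run_len = 0
            continue
        # candidate reversal
        if run_sign != s:
            run_sign = int(s)
            run_len = 1
            run_start = j
        else:
            run_len += 1
        if run_len >= hysteresis or j == len(d) - 1:
            boundaries.append(run_start)
            directions.append(cur)
            cur = int(s)
            run_sign = 0
            run_len = 0
    directions.append(cur if cur != 0 else 1)
    boundaries.append(len(e) - 1)

    # segments[i] = (boundaries[i], boundaries[i+1]); pair opposite-direction
    # neighbours into triangular cycles.  Cycles tile [0, len(e)) half-open.
    n_seg = len(boundaries) - 1
    cycles: list[tuple[int, int]] = []
    i = 0
    while i < n_seg:
        start = boundaries[i]
        if i + 1 < n_seg and directions[i + 1] != directions[i]:
            stop = boundaries[i + 2]
            i += 2
        else:
            stop = boundaries[i + 1]
            i += 1
        cycles.append((start, stop))
    a, _ = cycles[-1]
    cycles[-1] = (a, len(e))
    return cycles


@dataclass(frozen=True)
class Voltammogram:
    """A potential/current sweep with cycle segmentation and reference metadata.

    Parameters
    ----------
    potential : array of float
        Applied potential in volts versus `reference`.
    current : array of float
        Measured current in amperes, anodic (oxidation) positive.
    scan_rate : float
        Sweep rate in V/s, > 0.
    cycles : list of (start, stop)
        Half-open index ranges, one per sweep segment.  Detected from the
        trace when omitted.
    reference : str
        One of NHE, AgAgCl_sat, CuCuSO4, AgWire_calibrated.
    offset_to_nhe : float
        Volts to *add* to `potential` to express it versus NHE.
    meta : dict
        Free-form provenance (electrolyte, electrode diameter, ...).
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    cycles: tuple[tuple[int, int], ...] = ()
    reference: str = "NHE"
    offset_to_nhe: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "potential", e)
        object.__setattr__(self, "current", i)
        if e.ndim != 1 or i.ndim != 1 or e.size != i.size:
            raise ValueError("potential and current must be 1-D arrays of equal length")
        if e.size < 2:
            raise ValueError("a voltammogram needs at least 2 samples")
        if not (np.isfinite(e).all() and np.isfinite(i).all()):
            raise ValueError("potential and current must be finite (no NaN/inf samples)")
        if not (math.isfinite(self.scan_rate) and self.scan_rate > 0):
            raise ValueError(f"scan_rate must be > 0 V/s, got {self.scan_rate!r}")
        if self.reference not in KNOWN_REFERENCES:
            raise ReferenceError_(
                f"unknown reference {self.reference!r}; known: {sorted(KNOWN_REFERENCES)}"
            )
        off = self.offset_to_nhe
        if off is None:
            if self.reference in CALIBRATED_REFERENCES:
                raise ReferenceError_(
                    f"reference {self.reference!r} requires an explicit offset_to_nhe"
                )
            off = REFERENCE_OFFSETS_V[self.reference]
            object.__setattr__(self, "offset_to_nhe", float(off))
        if not math.isfinite(off):
            raise ReferenceError_("offset_to_nhe must be finite")
        if self.reference == "NHE" and off != 0.0:
            raise ValueError("a trace declared vs NHE must have zero offset")
        if not self.cycles:
            object.__setattr__(self, "cycles", tuple(detect_cycles(e)))
        else:
            cyc = tuple((int(a), int(b)) for a, b in self.cycles)
            for a, b in cyc:
                if not (0 <= a < b <= e.size):
                    raise ValueError(f"invalid cycle range ({a}, {b}) for {e.size} samples")
            object.__setattr__(self, "cycles", cyc)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Potential and current arrays of cycle ``k``."""
        a, b = self.cycles[k]
        return self.potential[a:b], self.current[a:b]


def to_nhe(v: Voltammogram) -> Voltammogram:
    """Shift all potentials by the stored offset so the trace reads vs NHE.

    Idempotent; currents are unchanged.
    """
    if v.reference == "NHE":
        return v
    return Voltammogram(
        potential=v.potential + v.offset_to_nhe,
        current=v.current,
        scan_rate=v.scan_rate,
        cycles=v.cycles,
        reference="NHE",
        offset_to_nhe=0.0,
        meta=dict(v.meta),
    )


_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(line: str) -> str | None:
    for dl in _DELIMITERS:
        if dl in line:
            return dl
    return None  # whitespace


def _parse_header_value(key: str, value: str, header: dict) -> None:
    key = key.strip()
    value = value.strip()
    if key.startswith("meta."):
        header.setdefault("meta", {})[key[5:]] = value
        return
    header[key] = value


def read_voltammogram(
    path: str | Path,
    dialect: str = "two_column_csv",
    scan_rate: float | None = None,
    reference: str | None = None,
    offset_to_nhe: float | None = None,
    sign: int = 1,
    delimiter: str | None = None,
) -> Voltammogram:
    """Read a delimited two-column voltammogram file.

    Explicit arguments override values found in the file header.  ``sign``
    flips the current column for instruments using the cathodic-positive
    convention (flip is logged).
    """
    path = Path(path)
    if dialect not in ("two_column_csv", "instrument_text"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")

    header: dict = {}
    pot: list[float] = []
    cur: list[float] = []
    n_bad = 0
    first_bad: tuple[int, str] | None = None
    in_data = False

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if dialect == "two_column_csv" and line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, val = body.partition("=")
                    _parse_header_value(k, val, header)
                continue
            if dialect == "instrument_text" and not in_data:
                # header block: bare key=value lines until numbers start
                stripped = line.lstrip("#").strip()
                token = stripped.split(_sniff_delimiter(stripped) or None)[0] if stripped else ""
                is_numeric = False
                try:
                    float(token)
                    is_numeric = True
                except ValueError:
                    pass
                if not is_numeric:
                    if "=" in stripped:
                        k, _, val = stripped.partition("=")
                        _parse_header_value(k, val, header)
                    continue
                in_data = True
            dl = delimiter or _sniff_delimiter(line)
            parts = line.split(dl) if dl else line.split()
            if len(parts) < 2:
                n_bad += 1
                first_bad = first_bad or (lineno, line)
                continue
            try:
                pot.append(float(parts[0]))
                cur.append(float(parts[1]))
            except ValueError:
                # column-label rows etc. are tolerated; counted and logged
                n_bad += 1
                first_bad = first_bad or (lineno, line)
                continue

    if n_bad:
        logger.info("%s: rejected %d non-numeric row(s), first at line %d", path, n_bad, first_bad[0])
    if not pot:
        assert first_bad is not None or n_bad == 0
        where = f" (first bad line {first_bad[0]}: {first_bad[1]!r})" if first_bad else ""
        raise VoltammogramFormatError(f"{path}: no numeric data rows{where}")
    if len(pot) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")

    if scan_rate is None:
        try:
            scan_rate = float(header["scan_rate_v_s"])
        except (KeyError, ValueError):
            raise ValueError(f"{path}: scan_rate not given and not found in header")
    if reference is None:
        reference = header.get("reference", "NHE")
    if offset_to_nhe is None and "offset_to_nhe_v" in header:
        offset_to_nhe = float(header["offset_to_nhe_v"])
    cycles: tuple[tuple[int, int], ...] = ()
    if "cycles" in header:
        cycles = tuple(
            (int(a), int(b))
            for a, b in (seg.split(":") for seg in header["cycles"].split(";") if seg)
        )
    if sign == -1:
        logger.info("%s: flipping current sign to anodic-positive convention", path)

    return Voltammogram(
        potential=np.asarray(pot),
        current=sign * np.asarray(cur),
        scan_rate=scan_rate,
        cycles=cycles,
        reference=reference,
        offset_to_nhe=offset_to_nhe,
        meta=header.get("meta", {}),
    )


def write_voltammogram(v: Voltammogram, path: str | Path, delimiter: str = ",") -> Path:
    """Write a voltammogram as two-column delimited text with a ``#`` header.

    The header carries scan rate, reference, offset and cycle boundaries so
    :func:`read_voltammogram` inverts the file exactly (float round trip via
    ``%.17g``).
    """
    if delimiter not in _DELIMITERS:
        raise ValueError(f"delimiter must be one of {_DELIMITERS}")
    path = Path(path)
    lines = [
        "# aunpcount voltammogram v1",
        f"# scan_rate_v_s = {v.scan_rate:.17g}",
        f"# reference = {v.reference}",
        f"# offset_to_nhe_v = {v.offset_to_nhe:.17g}",
        "# cycles = " + ";".join(f"{a}:{b}" for a, b in v.cycles),
    ]
    for k, val in sorted(v.meta.items()):
        lines.append(f"# meta.{k} = {val}")
    lines.append(f"potential_v{delimiter}current_a")
    for e, i in zip(v.potential, v.current):
        lines.append(f"{e:.17g}{delimiter}{i:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
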
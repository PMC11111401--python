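"""Radiocarbon calibration curves: reading, interpolation, and synthesis.

A calibration curve maps calendar age (cal BP, present = 1950) to the
expected conventional radiocarbon age (CRA) with a per-year 1-sigma
uncertainty. Published curves such as IntCal20 (northern hemisphere) and
SHCal20 (southern hemisphere) are distributed as comma-separated ``.14c``
files whose first three columns are cal BP, 14C age BP, and the 1-sigma
error; this module reads that dialect. No curve is bundled: tests and
simulations use :func:`synth_curve`, real curves are user-supplied paths.

Convention used throughout the package: calendar grids are stored in
*descending* cal BP (oldest year first), and intervals are closed
``[start, end]`` with ``start >= end`` in BP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalCurve", "CurveFormatError", "load_curve", "interpolate_curve", "synth_curve"]


class CurveFormatError(ValueError):
    """Raised when a calibration-curve file cannot be parsed or validated."""


@dataclass(frozen=True)
class CalCurve:
    """A calendar -> radiocarbon age mapping with per-year uncertainty.

    Parameters
    ----------
    name
        Label for the curve (e.g. ``"intcal20"`` or ``"synthetic"``).
    cal_bp
        Strictly monotone grid of calendar years BP.
    c14_age
        Mean radiocarbon age BP at each grid point.
    sigma_curve
        1-sigma curve uncertainty (14C years) at each grid point; >= 0.
    """

    name: str
    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma_curve: np.ndarray
    _ascending: tuple = field(init=False, repr=False, default=None)

    def __post_init__(self):
        cal = np.asarray(self.cal_bp, dtype=float)
        age = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.sigma_curve, dtype=float)
        if cal.ndim != 1 or len(cal) < 2:
            raise CurveFormatError("curve needs at least 2 grid points")
        if len(age) != len(cal) or len(sig) != len(cal):
            raise CurveFormatError("c14_age and sigma_curve must match cal_bp length")
        d = np.diff(cal)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CurveFormatError("cal_bp must be strictly monotone")
        if np.any(sig < 0):
            raise CurveFormatError("sigma_curve must be non-negative")
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "c14_age", age)
        object.__setattr__(self, "sigma_curve", sig)
        # cache ascending views for np.interp
        if cal[0] > cal[-1]:
            asc = (cal[::-1], age[::-1], sig[::-1])
        else:
            asc = (cal, age, sig)
        object.__setattr__(self, "_ascending", asc)

    @property
    def span(self) -> tuple:
        """(oldest, youngest) cal BP covered by the curve."""
        return float(self.cal_bp.max()), float(self.cal_bp.min())

    def c14_at(self, cal_bp) -> np.ndarray:
        """Linearly interpolated mean 14C age at arbitrary calendar years."""
        x, y, _ = self._ascending
        return np.interp(cal_bp, x, y)

    def sigma_at(self, cal_bp) -> np.ndarray:
        """Linearly interpolated curve 1-sigma at arbitrary calendar years."""
        x, _, s = self._ascending
        return np.interp(cal_bp, x, s)

    def is_annual(self) -> bool:
        """True if the grid step is exactly 1 calendar year (descending)."""
        return bool(np.all(np.diff(self.cal_bp) == -1))


def load_curve(path, dialect: str = "intcal14c", name: str | None = None) -> CalCurve:
    """Read a calibration curve from an IntCal-style ``.14c`` file.

    Lines beginning with ``#`` are comments; data lines are comma-separated
    with cal BP, 14C age, and 1-sigma error in the first three columns.
    Extra columns (Delta-14C etc.) are ignored. Row order is preserved.
    """
    if dialect != "intcal14c":
        raise ValueError(f"unknown curve dialect: {dialect!r}")
    cal, age, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(",")
            if len(parts) < 3:
                raise CurveFormatError(f"{path}: line {lineno}: expected >=3 comma-separated columns")
            try:
                cal.append(float(parts[0]))
                age.append(float(parts[1]))
                sig.append(float(parts[2]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    if len(cal) < 2:
        raise CurveFormatError(f"{path}: need at least 2 data rows, found {len(cal)}")
    return CalCurve(name=name or str(path), cal_bp=np.array(cal), c14_age=np.array(age), sigma_curve=np.array(sig))


def interpolate_curve(curve: CalCurve) -> CalCurve:
    """Resample a curve onto an exact 1-calendar-year grid.

    Both the mean age and the 1-sigma uncertainty are interpolated
    linearly, the standard practice in calibration software. Output grid
    is descending cal BP (oldest first) spanning the input range.
    Idempotent: interpolating an annual curve returns an equal curve.
    """
    old, young = curve.span
    grid = np.arange(np.floor(old), np.ceil(young) - 1, -1.0)
    grid = grid[(grid <= old) & (grid >= young)]
    return CalCurve(
        name=curve.name,
        cal_bp=grid,
        c14_age=curve.c14_at(grid),
        sigma_curve=curve.sigma_at(grid),
    )


def synth_curve(
    span: tuple,
    wiggle_amplitude: float = 0.0,
    wiggle_period: float = 500.0,
    sigma: float = 0.0,
    seed: int | None = None,
    name: str = "synthetic",
) -> CalCurve:
    """Build a synthetic calibration curve on a 1-year grid.

    The mean mapping is ``c14_age(t) = t + A * sin(2 pi t / P)``: with
    amplitude ``A = 0`` this is the identity curve, under which a CRA of
    ``m`` calibrates to a density centred on calendar year ``m``. The
    ``seed`` argument is reserved for optional noise variants and does not
    currently alter the deterministic closed form.

    Parameters
    ----------
    span
        (old_bp, young_bp) with old_bp > young_bp.
    wiggle_amplitude, wiggle_period
        Sinusoidal deviation (14C years) and its period (cal years).
    sigma
        Constant curve 1-sigma in 14C years.
    """
    old, young = span
    if not old > young:
        raise ValueError(f"span must satisfy old_bp > young_bp, got {span}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if wiggle_amplitude != 0 and wiggle_period <= 0:
        raise ValueError("wiggle_period must be positive when amplitude is non-zero")
    grid = np.arange(float(old), float(young) - 1, -1.0)
    if wiggle_amplitude != 0:
        age = grid + wiggle_amplitude * np.sin(2.0 * np.pi * grid / wiggle_period)
    else:
        age = grid.copy()
    return CalCurve(name=name, cal_bp=grid, c14_age=age, sigma_curve=np.full_like(grid, float(sigma)))
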
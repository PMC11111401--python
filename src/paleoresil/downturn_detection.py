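"""Posterior-predictive envelopes and extraction of downturn intervals.

A downturn is a maximal run of calendar years in which the observed SPD
falls strictly below the lower bound of a pointwise posterior-predictive
envelope of the fitted growth model. Each envelope replicate draws a
growth rate from the posterior, simulates as many calendar-dated events
as the observed dataset has bins, back-calibrates them through the
calibration curve with lab errors resampled from the observed ones,
calibrates and sums them into a replicate SPD; pointwise quantiles over
replicates form the envelope. Runs of ten years or fewer are discarded
as likely artefacts of the null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calcurves import CalCurve
from .calibration import SPDGrid
from .growth_model import GrowthModelParams, PosteriorSample, growth_density

__all__ = [
    "Envelope",
    "Downturn",
    "posterior_predictive_envelope",
    "detect_downturns",
    "drop_transition_adjacent",
]


@dataclass(frozen=True)
class Envelope:
    """Pointwise lower/upper quantiles of simulated SPDs on a 1-year grid."""

    cal_bp: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_sim: int

    def __post_init__(self):
        if np.any(self.lower > self.upper):
            raise ValueError("lower quantile exceeds upper somewhere")


@dataclass(frozen=True)
class Downturn:
    """One sub-envelope interval with its SPD landmarks.

    BP convention: T_start >= t_min >= T_end; duration = T_start - T_end;
    b is the SPD at the first sub-envelope year, x the minimum during the
    run, e the SPD at the last sub-envelope year.
    """

    region: str
    T_start: float
    T_end: float
    t_min: float
    b: float
    x: float
    e: float

    def __post_init__(self):
        if not (self.T_start >= self.t_min >= self.T_end):
            raise ValueError("require T_start >= t_min >= T_end (cal BP)")
        if self.x > self.b or self.x > self.e:
            raise ValueError("x must be the minimum of the run")

    @property
    def duration(self) -> float:
        return self.T_start - self.T_end

    @property
    def time_to_min(self) -> float:
        return self.T_start - self.t_min


def _simulate_spd(
    rng: np.random.Generator,
    r: float,
    n_dates: int,
    lab_errors: np.ndarray,
    curve: CalCurve,
    grid: np.ndarray,
    mu: np.ndarray,
    sig: np.ndarray,
    p_cal: np.ndarray,
) -> np.ndarray:
    """One envelope replicate: simulate, back-calibrate, calibrate, sum."""
    years = rng.choice(grid, size=n_dates, p=p_cal)
    errs = rng.choice(lab_errors, size=n_dates, replace=True)
    mu_y = np.interp(years, grid[::-1], mu[::-1])
    sig_y = np.interp(years, grid[::-1], sig[::-1])
    cras = rng.normal(mu_y, np.sqrt(errs**2 + sig_y**2))
    # vectorized calibration of all replicate dates over the region grid
    var = errs[:, None] ** 2 + sig[None, :] ** 2
    mass = np.exp(-0.5 * (cras[:, None] - mu[None, :]) ** 2 / var) / np.sqrt(2.0 * np.pi * var)
    peak = mass.max(axis=1, keepdims=True)
    mass[mass < 1e-7 * peak] = 0.0
    return mass.sum(axis=0)


def posterior_predictive_envelope(
    posterior: PosteriorSample,
    n_dates: int,
    lab_errors,
    curve: CalCurve,
    bounds: tuple,
    n_sim: int = 1000,
    level: float = 0.90,
    seed: int = 0,
) -> Envelope:
    """Pointwise posterior-predictive envelope of the fitted growth model.

    ``n_dates`` should equal the number of *bins* in the observed data
    (the SPD's effective sampling unit). ``level`` = 0.90 yields the
    5th/95th pointwise percentiles; ``level`` = 1.0 the per-year
    min/max over replicates. Deterministic given ``seed``.
    """
    if posterior.flat.size == 0:
        raise ValueError("posterior sample is empty")
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    lab_errors = np.asarray(lab_errors, dtype=float)
    a, b = float(bounds[0]), float(bounds[1])
    grid = np.arange(a, b - 1, -1.0)
    mu = curve.c14_at(grid)
    sig = curve.sigma_at(grid)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = posterior.flat
    sims = np.empty((n_sim, len(grid)))
    for k in range(n_sim):
        r = float(rng.choice(draws))
        f = growth_density(grid, GrowthModelParams(r=r, a=a, b=b))
        p_cal = f / f.sum()
        sims[k] = _simulate_spd(rng, r, n_dates, lab_errors, curve, grid, mu, sig, p_cal)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(sims, alpha, axis=0)
    upper = np.quantile(sims, 1.0 - alpha, axis=0)
    return Envelope(cal_bp=grid, lower=lower, upper=upper, level=level, n_sim=n_sim)


def detect_downturns(spd: SPDGrid, env: Envelope, min_duration: float = 10.0) -> list:
    """Extract downturns: maximal runs of years with SPD strictly below
    the envelope's lower bound, longer than ``min_duration`` years.

    For each surviving run, b = SPD at the first (oldest) sub-envelope
    year, x = minimum SPD over the run, e = SPD at the last year, and
    t_min = the year of x (oldest year on ties). Returned oldest-first.
    """
    if len(spd.cal_bp) != len(env.cal_bp) or not np.array_equal(spd.cal_bp, env.cal_bp):
        raise ValueError("SPD and envelope grids are misaligned")
    below = spd.spd < env.lower  # strict: tie years break runs
    downturns = []
    i = 0
    n = len(below)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        T_start, T_end = spd.cal_bp[i], spd.cal_bp[j]
        if T_start - T_end > min_duration:
            seg = spd.spd[i : j + 1]
            k = int(np.argmin(seg))  # argmin takes the first = oldest tie
            downturns.append(
                Downturn(
                    region=spd.region,
                    T_start=float(T_start),
                    T_end=float(T_end),
                    t_min=float(spd.cal_bp[i + k]),
                    b=float(seg[0]),
                    x=float(seg[k]),
                    e=float(seg[-1]),
                )
            )
        i = j + 1
    return downturns


def drop_transition_adjacent(downturns: list, breakpoints: list, margin: float = 0.0) -> list:
    """Remove downturns overlapping any [breakpoint - margin, breakpoint + margin].

    Downturns abutting a subsetting breakpoint can be artefacts of
    fitting the two segments separately; the default margin 0 drops only
    downturns whose interval contains the breakpoint itself.
    """
    kept = []
    for d in downturns:
        if any(d.T_start >= bp - margin and d.T_end <= bp + margin for bp in breakpoints):
            continue
        kept.append(d)
    return kept
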
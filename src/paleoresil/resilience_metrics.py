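"""Resistance, resilience, pace, and frequency metrics per downturn.

These are the dimensionless response metrics of the meta-analysis:

* resistance = 1 - 2|b-x| / (|b| + |b-x|) — depth of a downturn relative
  to its baseline; 1 means no change, 0 total collapse.
* resilience = 2|b-x| / (|b-x| + |b-e|) - 1 — recovery by the downturn's
  end relative to maximum impact; 1 full recovery, 0 none, negative when
  the end value overshoots the baseline.
* pace = time-to-minimum / duration — relative speed of decline; higher
  values are slower downturns.
* frequency — cumulative downturn count within a region per millennium
  of elapsed record, computed per downturn.

``assemble_table`` joins the detected downturns with expert annotations
(disturbance category and type, dominant land use, evidence of change)
into the cross-sectional analysis table.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .downturn_detection import Downturn

__all__ = [
    "resistance",
    "resilience",
    "pace",
    "downturn_frequency",
    "metrics_row",
    "assemble_table",
    "STUDY_TABLE_COLUMNS",
]

STUDY_TABLE_COLUMNS = [
    "region",
    "T_start",
    "T_end",
    "t_min",
    "b",
    "x",
    "e",
    "duration",
    "time_to_min",
    "resistance",
    "resilience",
    "pace",
    "n_downturn",
    "frequency",
    "log_frequency",
    "category",
    "dist_type",
    "land_use",
    "change",
]


def resistance(b: float, x: float) -> float:
    """Depth of a downturn relative to baseline; in [0, 1]."""
    if not b > 0:
        raise ValueError(f"baseline b must be > 0, got {b}")
    if x < 0:
        raise ValueError(f"minimum x must be >= 0, got {x}")
    drop = abs(b - x)
    return 1.0 - 2.0 * drop / (abs(b) + drop)


def resilience(b: float, x: float, e: float) -> float:
    """Rate of recovery to baseline, controlling for maximum impact.

    1 means the end value regained the baseline, 0 no recovery at all,
    negative values an overshoot past the baseline. Undefined (NaN is
    *not* returned — a ValueError is raised) when x = b, i.e. when no
    drop occurred; callers flag and exclude such rows.
    """
    if not b > 0:
        raise ValueError(f"baseline b must be > 0, got {b}")
    drop = abs(b - x)
    if drop == 0:
        raise ValueError("resilience undefined when x = b (no drop occurred)")
    return 2.0 * drop / (drop + abs(b - e)) - 1.0


def pace(time_to_min: float, duration: float) -> float:
    """Time to SPD minimum normalized by downturn duration; in [0, 1]."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not 0 <= time_to_min <= duration:
        raise ValueError("time_to_min must lie in [0, duration]")
    return time_to_min / duration


def downturn_frequency(region_downturns: list, region_start: float) -> list:
    """Per-downturn cumulative frequency, events per millennium.

    For the k-th downturn (oldest first), frequency is the cumulative
    count k normalized by the record elapsed from the region's older
    bound to that downturn's end: k / (region_start - T_end_k) * 1000.
    Returns a list of (frequency, log_frequency) pairs; the log is
    natural.
    """
    starts = [d.T_start for d in region_downturns]
    if any(s2 > s1 for s1, s2 in zip(starts, starts[1:])):
        raise ValueError("downturns must be sorted oldest first")
    out = []
    for k, d in enumerate(region_downturns, start=1):
        elapsed = region_start - d.T_end
        if elapsed <= 0:
            raise ValueError(
                f"downturn ending {d.T_end} not after region start {region_start}: zero elapsed time"
            )
        freq = k / elapsed * 1000.0
        out.append((freq, math.log(freq)))
    return out


def metrics_row(d: Downturn, n_downturn: int, frequency: float, log_frequency: float) -> dict:
    """All numeric metric columns for one downturn (no annotations)."""
    try:
        resil = resilience(d.b, d.x, d.e)
    except ValueError:
        resil = np.nan  # x = b guard: retained but flagged missing
    return {
        "region": d.region,
        "T_start": d.T_start,
        "T_end": d.T_end,
        "t_min": d.t_min,
        "b": d.b,
        "x": d.x,
        "e": d.e,
        "duration": d.duration,
        "time_to_min": d.time_to_min,
        "resistance": resistance(d.b, d.x),
        "resilience": resil,
        "pace": pace(d.time_to_min, d.duration) if d.duration > 0 else np.nan,
        "n_downturn": n_downturn,
        "frequency": frequency,
        "log_frequency": log_frequency,
    }


def assemble_table(
    downturns_by_region: dict,
    annotations: pd.DataFrame,
    region_starts: dict,
    tolerance: float = 10.0,
) -> pd.DataFrame:
    """Join per-region downturns with annotations into the study table.

    ``downturns_by_region`` maps region -> list of Downturn (any order;
    sorted oldest-first here). ``annotations`` needs columns region,
    T_start, category, dist_type, land_use, change; a row matches a
    downturn when regions agree and |T_start difference| <= tolerance.
    ``region_starts`` maps region -> older record bound (cal BP) used
    for the frequency denominator. Raises on any unmatched downturn.
    """
    required = {"region", "T_start", "category", "dist_type", "land_use", "change"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    rows = []
    unmatched = []
    for region, downturns in downturns_by_region.items():
        downturns = sorted(downturns, key=lambda d: -d.T_start)
        freqs = downturn_frequency(downturns, region_starts[region])
        ann = annotations[annotations["region"] == region]
        for k, (d, (f, lf)) in enumerate(zip(downturns, freqs), start=1):
            row = metrics_row(d, k, f, lf)
            match = ann[(ann["T_start"] - d.T_start).abs() <= tolerance]
            if len(match) == 0:
                unmatched.append(f"{region} @ T_start={d.T_start}")
                continue
            m = match.iloc[0]
            row.update(
                category=m["category"],
                dist_type=m["dist_type"],
                land_use=m["land_use"],
                change=bool(m["change"]),
            )
            rows.append(row)
    if unmatched:
        raise ValueError("downturns without a matching annotation: " + "; ".join(unmatched))
    return pd.DataFrame(rows, columns=STUDY_TABLE_COLUMNS)
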
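"""Social-approach scoring: zone occupancy, exclusion, difference scores.

A subject's social approach is quantified as the time its head tip spends
inside a 10 mm-wide zone along the inner wall on the display side.  The
session is a 1-min baseline (no stimulus) followed by 5 min of stimulus
presentation.  Subjects that already sit in the zone for more than 55 s of
the baseline are excluded (ceiling effect: no headroom to express
attraction).  The response measure is the per-minute *difference score* —
that stimulus minute's occupancy minus the baseline occupancy — so each
subject serves as its own control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import OccupancyTrace

__all__ = [
    "occupancy_time",
    "score_subjects",
    "exclude_baseline",
    "difference_scores",
]

ZONE_MM = 10.0
EXCLUSION_THRESHOLD_S = 55.0


def occupancy_time(
    trace: OccupancyTrace,
    interval_s: tuple[float, float],
    zone_mm: float = ZONE_MM,
) -> float:
    """Seconds spent with the head within ``zone_mm`` of the display wall.

    ``interval_s`` is half-open ``[t0, t1)`` in seconds from session start.
    Frames with missing (NaN) positions are dropped from both numerator and
    denominator and the occupancy is rescaled to the interval length, so a
    few tracking dropouts do not bias the score downward.
    """
    t0, t1 = interval_s
    if not 0 <= t0 < t1 <= trace.n_frames / trace.fps:
        raise ValueError(f"interval {interval_s} outside trace or empty")
    f0, f1 = int(round(t0 * trace.fps)), int(round(t1 * trace.fps))
    window = trace.distance_mm[f0:f1]
    valid = ~np.isnan(window)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return float("nan")
    frac_in = float((window[valid] <= zone_mm).sum()) / n_valid
    return frac_in * (t1 - t0)


def score_subjects(
    traces: list[OccupancyTrace],
    zone_mm: float = ZONE_MM,
    n_stimulus_bins: int = 5,
) -> pd.DataFrame:
    """Per-subject occupancy table: baseline plus per-minute stimulus bins.

    Returns a DataFrame with one row per subject and columns ``subject``,
    ``group``, ``baseline_s``, ``min1_s`` .. ``min5_s`` (seconds in zone in
    each half-open stimulus minute) and ``dropout_frames``.
    """
    rows = []
    for tr in traces:
        base = occupancy_time(tr, (0.0, tr.baseline_s), zone_mm)
        row = {
            "subject": tr.subject,
            "group": tr.group,
            "baseline_s": base,
            "dropout_frames": int(np.isnan(tr.distance_mm).sum()),
        }
        for m in range(n_stimulus_bins):
            t0 = tr.baseline_s + 60.0 * m
            row[f"min{m + 1}_s"] = occupancy_time(tr, (t0, t0 + 60.0), zone_mm)
        rows.append(row)
    return pd.DataFrame(rows)


def exclude_baseline(
    table: pd.DataFrame, threshold_s: float = EXCLUSION_THRESHOLD_S
) -> pd.DataFrame:
    """Flag subjects whose baseline occupancy is strictly over the threshold.

    "Over 55 s" is read as a strict inequality: a subject at exactly 55.0 s
    is retained.  Returns a copy with a boolean ``excluded`` column; no rows
    are dropped, so the caller can audit who was excluded and why.
    """
    out = table.copy()
    out["excluded"] = out["baseline_s"] > threshold_s
    return out


def difference_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-minute difference scores: stimulus-minute occupancy - baseline.

    Adds ``dmin1_s`` .. ``dmin5_s`` (signed seconds, bounded by ±60 s) for
    the retained subjects; excluded subjects keep NaN difference scores.
    Requires :func:`exclude_baseline` to have run first.
    """
    if "excluded" not in table.columns:
        raise ValueError("run exclude_baseline before computing difference scores")
    out = table.copy()
    minute_cols = [c for c in out.columns if c.startswith("min") and c.endswith("_s")]
    for c in minute_cols:
        d = out[c] - out["baseline_s"]
        d[out["excluded"]] = np.nan
        out["d" + c] = d
    return out


def scores_to_long(table: pd.DataFrame, include_baseline: bool = True) -> pd.DataFrame:
    """Reshape retained subjects' difference scores into ANOVA long format.

    Time levels are ``baseline`` followed by ``min1`` .. ``min5``; the score
    at each level is that level's occupancy minus the baseline occupancy, so
    the baseline level carries 0 by construction (each subject is its own
    control).  Columns: subject, group, time, score.
    """
    kept = table.loc[~table["excluded"]].copy()
    recs = []
    minute_cols = [c for c in kept.columns if c.startswith("dmin")]
    for _, row in kept.iterrows():
        if include_baseline:
            recs.append(
                {"subject": row["subject"], "group": row["group"], "time": "baseline", "score": 0.0}
            )
        for c in minute_cols:
            recs.append(
                {
                    "subject": row["subject"],
                    "group": row["group"],
                    "time": c[1:-2],
                    "score": row[c],
                }
            )
    return pd.DataFrame(recs)
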
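"""Response construction: 60-s rolling sums and per-assay group means.

The response variable of the downstream model is, for each assay and each
group of an experimental factor, the mean over fish of the total distance
moved during the trailing minute, evaluated every second (mm/min).  Seconds
before the first complete window are flagged invalid rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError
from .schedule import PhotoSchedule

__all__ = [
    "ActivityTable",
    "load_tracking",
    "rolling_sum",
    "group_mean_series",
    "downsample",
    "attach_analysis_time",
]

REQUIRED_COLUMNS = ("assay_id", "fish_id", "time_s", "dist_mm")

# canonical orderings for known factors (reference level first)
CANONICAL_LEVELS = {
    "genotype": ["WT", "HT", "HM"],
    "geno": ["WT", "HT", "HM"],
    "illumination": ["dark", "light"],
    "illu": ["dark", "light"],
}


@dataclass
class ActivityTable:
    """Validated long-format per-second per-fish displacement table."""

    data: pd.DataFrame
    factors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"activity table missing required columns: {missing}")
        for f in self.factors:
            if f not in self.data.columns:
                raise SchemaError(f"declared factor column {f!r} not in table")


def load_tracking(path, factors: list[str] | None = None) -> ActivityTable:
    """Read and validate a tracking CSV.

    Columns beyond ``assay_id, fish_id, time_s, dist_mm`` are treated as
    group factors unless ``factors`` names them explicitly.  Known factors
    (genotype, illumination) get a canonical categorical ordering with the
    reference level first.
    """
    df = pd.read_csv(path)
    return validate_activity(df, factors)


def validate_activity(df: pd.DataFrame, factors: list[str] | None = None) -> ActivityTable:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tracking table missing required columns: {missing}")
    if factors is None:
        factors = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    df = df.copy()
    df["time_s"] = df["time_s"].astype(np.int64)
    df["dist_mm"] = df["dist_mm"].astype(float)

    bad = df.index[df["dist_mm"] < 0]
    if len(bad):
        raise DataValidationError(f"negative dist_mm at rows {bad[:5].tolist()}")
    dup = df.duplicated(subset=["assay_id", "fish_id", "time_s"])
    if dup.any():
        rows = df.index[dup][:5].tolist()
        raise DataValidationError(f"duplicated (assay, fish, time) records at rows {rows}")

    for f in factors:
        levels = CANONICAL_LEVELS.get(f)
        observed = pd.unique(df[f].astype(str))
        if levels and set(observed) <= set(levels):
            order = [l for l in levels if l in set(observed)]
        else:
            order = sorted(observed)
        df[f] = pd.Categorical(df[f].astype(str), categories=order, ordered=False)

    return ActivityTable(df, list(factors))


def rolling_sum(values, window_s: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Trailing rolling sum over ``window_s`` seconds of a contiguous series.

    Returns ``(rsum, valid)`` arrays of the input length: ``rsum[t]`` is the
    sum over seconds ``t-window_s+1 .. t`` and is valid only once a full
    window is available.  With per-second input this is mm/min for
    ``window_s=60``.
    """
    x = np.asarray(values, dtype=float)
    if window_s < 1:
        raise DataValidationError("window_s must be >= 1")
    n = x.size
    # extended-precision running sum: differencing large cumulative totals
    # must not lose relative accuracy on near-zero window sums
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=np.longdouble)])
    rsum = np.full(n, np.nan)
    if n >= window_s:
        rsum[window_s - 1 :] = (csum[window_s:] - csum[:-window_s]).astype(float)
    valid = ~np.isnan(rsum)
    rsum[~valid] = np.nan
    return rsum, valid


def _check_grid(times: np.ndarray, context: str) -> None:
    if times.size and not np.array_equal(np.diff(times), np.ones(times.size - 1, dtype=times.dtype)):
        raise DataValidationError(f"{context}: time grid has gaps or is unordered")


def group_mean_series(
    table: ActivityTable, window_s: int = 60, factors: list[str] | None = None
) -> pd.DataFrame:
    """Per-assay, per-group mean rolling-sum series (the model's response).

    Group means over fish are taken first, then the rolling window is applied
    (exactly equal to averaging per-fish rolling sums on a shared grid).
    Returns a tidy frame: assay_id, factor columns, time_s, rsum, valid.
    """
    factors = list(table.factors if factors is None else factors)
    df = table.data
    out_frames = []
    group_cols = ["assay_id", *factors]
    for keys, sub in df.groupby(group_cols, observed=True, sort=True):
        if sub.empty:
            continue
        pivot = sub.pivot_table(index="time_s", columns="fish_id", values="dist_mm", observed=True)
        if pivot.isna().any().any():
            raise DataValidationError(
                f"group {keys}: fish do not share a common time grid"
            )
        times = pivot.index.to_numpy()
        _check_grid(times, f"group {keys}")
        mean_disp = pivot.to_numpy().mean(axis=1)
        rsum, valid = rolling_sum(mean_disp, window_s)
        rec = {"assay_id": keys[0] if isinstance(keys, tuple) else keys}
        if isinstance(keys, tuple):
            for name, val in zip(factors, keys[1:]):
                rec[name] = val
        out_frames.append(
            pd.DataFrame({**rec, "time_s": times, "rsum": rsum, "valid": valid})
        )
    if not out_frames:
        raise DataValidationError("no groups found in activity table")
    out = pd.concat(out_frames, ignore_index=True)
    for f in factors:
        if isinstance(df[f].dtype, pd.CategoricalDtype):
            out[f] = pd.Categorical(out[f], categories=df[f].cat.categories)
    return out


def downsample(series: pd.DataFrame, step_s: int = 30) -> pd.DataFrame:
    """Keep every ``step_s``-th second starting from each series' first valid second."""
    if step_s < 1:
        raise DataValidationError("step_s must be >= 1")
    if step_s == 1:
        return series.copy()
    group_cols = [c for c in series.columns if c not in ("time_s", "rsum", "valid")]
    kept = []
    for _, sub in series.groupby(group_cols, observed=True, sort=False):
        sub = sub.sort_values("time_s")
        valid_times = sub.loc[sub["valid"], "time_s"]
        if valid_times.empty:
            continue
        t0 = int(valid_times.iloc[0])
        keep = (sub["time_s"] >= t0) & ((sub["time_s"] - t0) % step_s == 0)
        kept.append(sub[keep])
    if not kept:
        return series.iloc[0:0].copy()
    return pd.concat(kept, ignore_index=True)


def attach_analysis_time(series: pd.DataFrame, schedule: PhotoSchedule) -> pd.DataFrame:
    """Add the 1-based analyzed ``Time`` column (Time = time_s - origin).

    Rows at or before the analysis origin (acclimation) get Time <= 0 and are
    conventionally excluded from modeling.
    """
    out = series.copy()
    out["Time"] = out["time_s"].astype(np.int64) - schedule.analysis_origin_s
    return out
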
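"""Quality control and gridding of raw vital-sign observations.

Pipeline order is fixed: plausibility filter -> winsorize (raw observations,
per channel) -> hourly aggregation -> imputation / exclusion -> Z-score
standardization.  Winsorizing raw values before averaging prevents a single
artifactual spike from contaminating an hourly mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traj2targets.config import CHANNELS, PlausibilityRanges

N_HOURS = 12


class InputError(ValueError):
    """Raised for malformed analysis inputs."""


@dataclass
class GridSet:
    """Per-subject 6-channel x 12-hour matrices with an observed-cell mask.

    Hour bin ``h`` covers [h, h+1) from ICU admission. ``values`` has shape
    (N, n_channels, 12) with NaN where ``mask`` is False.
    """

    subject_ids: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        expected = (n, len(self.channels), N_HOURS)
        if self.values.shape != expected or self.mask.shape != expected:
            raise InputError(f"grid arrays must have shape {expected}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_long(self) -> pd.DataFrame:
        n, v, t = self.values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, v * t),
                "channel": np.tile(np.repeat(np.asarray(self.channels, object), t), n),
                "hour": np.tile(np.arange(t), n * v),
                "value": self.values.ravel(),
                "observed": self.mask.ravel(),
            }
        )


@dataclass
class StandardizationParams:
    """Pooled per-channel mean/SD over retained subject-hours."""

    mean: np.ndarray
    sd: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def inverse(self, standardized: np.ndarray, channel_index: int) -> np.ndarray:
        return standardized * self.sd[channel_index] + self.mean[channel_index]

    def to_dict(self) -> dict:
        return {
            ch: {"mean": float(m), "sd": float(s)}
            for ch, m, s in zip(self.channels, self.mean, self.sd)
        }


def plausibility_filter(
    vitals: pd.DataFrame, ranges: PlausibilityRanges | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop observations outside the (inclusive) per-channel plausibility bounds.

    Returns the filtered table and a per-channel count of removals.  Rows are
    dropped rather than NaN-ed: a removed observation simply no longer
    contributes to its hourly mean, which becomes missing if the bin empties.
    """
    ranges = ranges or PlausibilityRanges()
    report = {ch: 0 for ch in CHANNELS}
    keep = np.ones(len(vitals), dtype=bool)
    values = vitals["value"].to_numpy()
    channels = vitals["channel"].to_numpy()
    for ch in np.unique(channels):
        lo, hi = ranges.bounds(str(ch))
        sel = channels == ch
        bad = sel & ((values < lo) | (values > hi))
        report[str(ch)] = int(bad.sum())
        keep &= ~bad
    return vitals.loc[keep].reset_index(drop=True), report


def winsorize(
    x: np.ndarray, lower_q: float = 0.01, upper_q: float = 0.99
) -> np.ndarray:
    """Clip to the [lower_q, upper_q] empirical quantiles.

    Quantiles use linear interpolation between order statistics, so on the
    grid 0..100 the 1st/99th percentiles are exactly 1 and 99.
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        warnings.warn("winsorize skipped: fewer than 2 finite values")
        return x.copy()
    lo, hi = np.quantile(x[finite], [lower_q, upper_q])
    return np.clip(x, lo, hi)


def winsorize_vitals(
    vitals: pd.DataFrame, lower_q: float = 0.01, upper_q: float = 0.99
) -> pd.DataFrame:
    """Winsorize raw observations per channel across the cohort."""
    out = vitals.copy()
    for ch in out["channel"].unique():
        sel = out["channel"] == ch
        out.loc[sel, "value"] = winsorize(
            out.loc[sel, "value"].to_numpy(), lower_q, upper_q
        )
    return out


def hourly_aggregate(vitals: pd.DataFrame, horizon: int = N_HOURS) -> GridSet:
    """Mean of observations per subject-channel-hour bin over [0, horizon).

    Bin h is the half-open interval [h, h+1); an observation at time exactly
    h belongs to bin h.  Observations at time >= horizon are ignored; empty
    bins are missing.
    """
    unknown = ~vitals["channel"].isin(CHANNELS)
    if unknown.any():
        row = vitals.index[unknown][0]
        raise InputError(
            f"unknown channel {vitals.loc[row, 'channel']!r} in vitals row {row}"
        )
    if (vitals["time_hr"] < 0).any():
        raise InputError("observation times must be >= 0")

    sub = vitals[vitals["time_hr"] < horizon].copy()
    sub["hour"] = np.floor(sub["time_hr"]).astype(int)
    subject_ids = np.sort(vitals["subject_id"].unique())
    n = len(subject_ids)
    sid_index = {s: i for i, s in enumerate(subject_ids)}

    values = np.full((n, len(CHANNELS), horizon), np.nan)
    means = sub.groupby(["subject_id", "channel", "hour"], sort=False)["value"].mean()
    for (sid, ch, hour), m in means.items():
        values[sid_index[sid], CHANNELS.index(ch), hour] = m
    mask = ~np.isnan(values)
    return GridSet(subject_ids=subject_ids, values=values, mask=mask)


def _runs_of_missing(mask_row: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal missing run in a 12-bin mask row."""
    runs = []
    t = 0
    T = len(mask_row)
    while t < T:
        if not mask_row[t]:
            start = t
            while t < T and not mask_row[t]:
                t += 1
            runs.append((start, t - start))
        else:
            t += 1
    return runs


def _fill_channel(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill one channel row per the imputation rules; assumes it is retainable.

    Interior runs of length 1-2 (observed neighbors both sides) -> linear
    interpolation; longer interior runs -> carry last observation forward;
    trailing runs -> LOCF; leading runs -> next observation carried backward.
    """
    out = vals.copy()
    T = len(out)
    for start, length in _runs_of_missing(mask):
        end = start + length  # first index after the run
        if start == 0:
            out[:end] = out[end]  # leading: backfill
        elif end == T:
            out[start:] = out[start - 1]  # trailing: LOCF
        elif length <= 2:
            left, right = out[start - 1], out[end]
            for j in range(length):
                out[start + j] = left + (right - left) * (j + 1) / (length + 1)
        else:
            out[start:end] = out[start - 1]  # long interior: LOCF
    return out


def impute_grid(grids: GridSet, max_gap: int = 4) -> tuple[GridSet, pd.DataFrame]:
    """Fill retained grids and exclude subjects violating the gap rule.

    A subject is excluded if ANY channel has a run of more than ``max_gap``
    consecutive missing hours (reason ``long_gap``) or a channel with no
    observations at all (reason ``empty_channel``).  Retained grids come back
    complete; observed cells are never altered.
    """
    keep_rows = []
    exclusions = []
    filled = grids.values.copy()
    for i, sid in enumerate(grids.subject_ids):
        reason = None
        for ci, ch in enumerate(grids.channels):
            mask_row = grids.mask[i, ci]
            if not mask_row.any():
                reason = "empty_channel"
                break
            if max((length for _, length in _runs_of_missing(mask_row)), default=0) > max_gap:
                reason = "long_gap"
                break
        if reason is not None:
            exclusions.append((sid, reason))
            continue
        for ci in range(len(grids.channels)):
            filled[i, ci] = _fill_channel(filled[i, ci], grids.mask[i, ci])
        keep_rows.append(i)

    keep_rows = np.asarray(keep_rows, dtype=int)
    retained = GridSet(
        subject_ids=grids.subject_ids[keep_rows],
        values=filled[keep_rows],
        mask=np.ones((len(keep_rows), len(grids.channels), N_HOURS), dtype=bool),
        channels=grids.channels,
    )
    excl = pd.DataFrame(exclusions, columns=["subject_id", "reason"])
    return retained, excl


def standardize(grids: GridSet) -> tuple[GridSet, StandardizationParams]:
    """Z-score each channel against its pooled mean/SD over all subject-hours."""
    if not grids.mask.all():
        raise InputError("standardize requires complete (post-imputation) grids")
    mean = grids.values.mean(axis=(0, 2))
    sd = grids.values.std(axis=(0, 2), ddof=0)
    for ci, s in enumerate(sd):
        if s <= 0:
            raise InputError(
                f"channel {grids.channels[ci]!r} is constant; cannot standardize"
            )
    z = (grids.values - mean[None, :, None]) / sd[None, :, None]
    out = GridSet(
        subject_ids=grids.subject_ids,
        values=z,
        mask=grids.mask.copy(),
        channels=grids.channels,
    )
    return out, StandardizationParams(mean=mean, sd=sd, channels=grids.channels)


@dataclass
class PreprocessResult:
    grids: GridSet
    params: StandardizationParams
    exclusions: pd.DataFrame
    plausibility_report: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.grids.n_subjects


def run_preprocess(
    vitals: pd.DataFrame,
    ranges: PlausibilityRanges | None = None,
    lower_q: float = 0.01,
    upper_q: float = 0.99,
) -> PreprocessResult:
    """Full QC protocol from raw long-format vitals to standardized grids."""
    filtered, report = plausibility_filter(vitals, ranges)
    clipped = winsorize_vitals(filtered, lower_q, upper_q)
    raw_grids = hourly_aggregate(clipped)
    complete, exclusions = impute_grid(raw_grids)
    standardized, params = standardize(complete)
    return PreprocessResult(
        grids=standardized,
        params=params,
        exclusions=exclusions,
        plausibility_report=report,
    )
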
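"""Seeded synthetic ICU cohorts with known latent structure.

The generator emulates the data model the downstream analysis assumes: three
latent vital-sign trajectory groups with distinct polynomial mean curves,
group-dependent Weibull survival hazards, blood gas values whose excess
ICU-mortality risk is U-shaped around a known risk-minimizing interval,
raw observations at 2-4 jittered timestamps per hour, injectable
missingness (independent holes plus long runs) and implausible outliers.
Ground-truth labels and intervals travel in a sidecar object and are never
joined into the emitted analysis tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from traj2targets.config import (
    CHANNELS,
    GAS_PARAMETERS,
    ConfigurationError,
    GasParam,
    SyntheticConfig,
    default_gas_params,
)

HORIZONS: Mapping[str, float] = {"28d": 28.0, "90d": 90.0, "365d": 365.0}

# covariate effects on the long-horizon log hazard and the ICU-death logit;
# kept mild so the group contrast dominates both outcomes
_AGE_LOGHR = 0.004
_SOFA_LOGHR = 0.02
_AGE_LOGOR = 0.010
_SOFA_LOGOR = 0.06


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Independent stream per generator stage, all derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, stage)))


@dataclass
class SyntheticTruth:
    """Ground truth withheld from the analysis inputs."""

    group_label: np.ndarray  # 1..K per subject
    survival_time: np.ndarray  # latent event time, days
    icu_death: np.ndarray  # 0/1
    gas_intervals: dict[str, tuple[float, float]]
    mixing: tuple[float, ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_label": self.group_label.tolist(),
                "survival_time": np.round(self.survival_time, 6).tolist(),
                "icu_death": self.icu_death.tolist(),
                "gas_intervals": {k: list(v) for k, v in self.gas_intervals.items()},
                "mixing": list(self.mixing),
                "seed": self.seed,
            },
            indent=1,
        )


@dataclass
class MissingnessRecord:
    """Bookkeeping of injected holes, for exact downstream verification."""

    deleted_cells: pd.DataFrame  # subject_id, channel, hour
    long_gaps: pd.DataFrame  # subject_id, channel, start_hour, length


@dataclass
class OutlierRecord:
    """Which observations were replaced by implausible values."""

    positions: pd.DataFrame  # obs_id, subject_id, channel, original, injected


def default_scenario(n_subjects: int = 600, seed: int = 0, **overrides) -> SyntheticConfig:
    """Three-group scenario mirroring the qualitative cluster signatures.

    Group 1 is hypertensive (elevated SBP/DBP/MAP), group 2 hyperinflammatory
    (elevated HR/RR with reduced SpO2) and group 3 hypo-inflammatory (low
    pressures, high SpO2).  Every pair of groups is separated by at least two
    residual SDs in at least one channel at the trajectory midpoint.
    """
    # rows: channels HR, RR, SBP, DBP, MAP, SpO2; cols: intercept..cubic in raw hours
    g1 = np.array(
        [
            [88.0, 0.3, 0.0, 0.0],
            [18.0, 0.1, 0.0, 0.0],
            [152.0, -1.2, 0.05, 0.0],
            [86.0, -0.5, 0.0, 0.0],
            [106.0, -0.8, 0.03, 0.0],
            [96.5, 0.05, 0.0, 0.0],
        ]
    )
    g2 = np.array(
        [
            [112.0, 1.5, -0.08, 0.0],
            [28.0, 0.3, -0.015, 0.0],
            [112.0, -0.5, 0.0, 0.0],
            [60.0, -0.2, 0.0, 0.0],
            [76.0, -0.3, 0.0, 0.0],
            [91.5, 0.15, -0.01, 0.0],
        ]
    )
    g3 = np.array(
        [
            [80.0, -0.2, 0.0, 0.0],
            [16.0, 0.0, 0.0, 0.0],
            [105.0, 0.3, 0.0, 0.0],
            [55.0, 0.1, 0.0, 0.0],
            [71.0, 0.2, 0.0, 0.0],
            [97.8, 0.02, 0.0, 0.0],
        ]
    )
    noise = np.array(
        [
            [8.0, 3.0, 10.0, 7.0, 8.0, 1.5],
            [8.0, 3.0, 10.0, 7.0, 8.0, 1.5],
            [8.0, 3.0, 10.0, 7.0, 8.0, 1.5],
        ]
    )
    kwargs = dict(
        n_subjects=n_subjects,
        mixing=(0.24, 0.35, 0.41),
        traj_coeffs=np.stack([g1, g2, g3]),
        noise_sd=noise,
        gas_params=default_gas_params(),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(64.0, 15.0, n), 18.0, 89.0).round(1)
    sex = (rng.random(n) < 0.60).astype(int)  # 1 = male
    race = rng.choice(["white", "black", "other"], size=n, p=(0.60, 0.25, 0.15))
    sofa = np.clip(rng.poisson(7.0, n), 0, 24)
    aps_iii = np.clip(rng.normal(50.0, 15.0, n), 5.0, 150.0).round(1)
    vent = (rng.random(n) < 0.78).astype(int)
    crrt = (rng.random(n) < 0.18).astype(int)
    rrt = np.where(crrt == 1, 1, (rng.random(n) < 0.05).astype(int))
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "sofa": sofa,
            "aps_iii": aps_iii,
            "invasive_vent": vent,
            "crrt": crrt,
            "rrt": rrt,
        }
    )


def _draw_gases(
    n: int, gas_params: Mapping[str, GasParam], rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name in GAS_PARAMETERS:
        p = gas_params[name]
        x = rng.normal(p.mean, p.sd, n)
        # redraw out-of-truncation values (simple rejection; bounds are wide)
        bad = (x < p.trunc_lo) | (x > p.trunc_hi)
        while bad.any():
            x[bad] = rng.normal(p.mean, p.sd, int(bad.sum()))
            bad = (x < p.trunc_lo) | (x > p.trunc_hi)
        cols[name] = np.round(x, 4)
    return pd.DataFrame(cols)


def _weibull_times(
    lp: np.ndarray, scale: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sample from a Weibull proportional-hazards model."""
    e = rng.exponential(1.0, lp.shape[0])
    return scale * (e / np.exp(lp)) ** (1.0 / shape)


def generate_cohort(
    config: SyntheticConfig, include_vitals: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (vitals long table, cohort table, truth sidecar).

    Identical config (including seed) gives byte-identical tables.  With
    ``include_vitals=False`` the (expensive) raw vital-sign table is skipped
    and an empty frame returned instead; everything else is unchanged.
    """
    gas_params = dict(config.gas_params) if config.gas_params else default_gas_params()
    n = config.n_subjects
    K = config.n_groups

    rng = _rng(config.seed, 0)
    labels = rng.choice(K, size=n, p=np.asarray(config.mixing, dtype=float)) + 1

    cov = _draw_covariates(n, rng)
    gases = _draw_gases(n, gas_params, rng)

    # long-horizon survival: Weibull PH in group + mild covariate effects
    lp = (
        np.asarray(config.group_loghr)[labels - 1]
        + _AGE_LOGHR * (cov["age"].to_numpy() - 64.0)
        + _SOFA_LOGHR * (cov["sofa"].to_numpy() - 7.0)
    )
    t_latent = _weibull_times(lp, config.hazard_scale, config.hazard_shape, rng)
    censor = np.full(n, config.admin_horizon_days)
    early = rng.random(n) < config.censor_rate
    censor[early] = rng.uniform(1.0, config.admin_horizon_days, int(early.sum()))

    # ICU death: logistic in covariates, group shift and U-shaped gas excess risk
    logit = (
        config.icu_logit_base
        + np.asarray(config.group_logor)[labels - 1]
        + _AGE_LOGOR * (cov["age"].to_numpy() - 64.0)
        + _SOFA_LOGOR * (cov["sofa"].to_numpy() - 7.0)
    )
    for name in GAS_PARAMETERS:
        logit = logit + gas_params[name].excess_risk(gases[name].to_numpy())
    p_icu = 1.0 / (1.0 + np.exp(-logit))
    icu_death = (rng.random(n) < p_icu).astype(int)

    # ICU time axis: days to ICU death, censored at discharge otherwise
    icu_los = np.maximum(1.0, np.ceil(rng.exponential(8.0, n)))
    icu_death_day = np.maximum(1.0, np.ceil(rng.exponential(6.0, n)))
    time_icu = np.where(icu_death == 1, icu_death_day, icu_los)

    cohort = pd.DataFrame({"subject_id": np.arange(1, n + 1)})
    cohort = pd.concat([cohort, cov, gases], axis=1)
    cohort["time_icu"] = time_icu
    cohort["event_icu"] = icu_death
    for hz, days in HORIZONS.items():
        t_obs = np.minimum(np.minimum(t_latent, censor), days)
        cohort[f"time_{hz}"] = np.maximum(1.0, np.ceil(t_obs))
        cohort[f"event_{hz}"] = (
            (t_latent <= np.minimum(censor, days)).astype(int)
        )

    if include_vitals:
        vitals = _emit_vitals(config, labels)
    else:
        vitals = pd.DataFrame(
            columns=["obs_id", "subject_id", "time_hr", "channel", "value"]
        )

    truth = SyntheticTruth(
        group_label=labels,
        survival_time=t_latent,
        icu_death=icu_death,
        gas_intervals={
            name: (gas_params[name].safe_lo, gas_params[name].safe_hi)
            for name in GAS_PARAMETERS
        },
        mixing=tuple(config.mixing),
        seed=config.seed,
    )
    return vitals, cohort, truth


def _emit_vitals(config: SyntheticConfig, labels: np.ndarray) -> pd.DataFrame:
    """Raw observations: 2-4 per subject-hour-channel with jittered times.

    Values are the group-mean polynomial evaluated at the hour index plus
    Gaussian channel noise, so hourly means are unbiased for the group curve.
    """
    rng = _rng(config.seed, 3)
    n = config.n_subjects
    lo, hi = config.obs_per_hour
    rows_subject, rows_time, rows_channel, rows_value = [], [], [], []
    hours = np.arange(12)
    for ci, ch in enumerate(CHANNELS):
        # per-group mean curve over the 12 hourly bins
        curves = np.stack(
            [config.mean_trajectory(g, ch, hours) for g in range(config.n_groups)]
        )
        sds = config.noise_sd[:, ci]
        counts = rng.integers(lo, hi + 1, size=(n, 12))
        total = int(counts.sum())
        subj_rep = np.repeat(np.arange(n), counts.sum(axis=1))
        hour_rep = np.concatenate(
            [np.repeat(hours, counts[i]) for i in range(n)]
        )
        jitter = rng.random(total)
        values = (
            curves[labels[subj_rep] - 1, hour_rep]
            + rng.normal(0.0, 1.0, total) * sds[labels[subj_rep] - 1]
        )
        if ch == "SpO2":  # physical ceiling of pulse oximetry
            values = np.minimum(values, 100.0)
        rows_subject.append(subj_rep + 1)
        rows_time.append(hour_rep + jitter)
        rows_channel.append(np.full(total, ch, dtype=object))
        rows_value.append(values)
    vitals = pd.DataFrame(
        {
            "subject_id": np.concatenate(rows_subject),
            "time_hr": np.round(np.concatenate(rows_time), 4),
            "channel": np.concatenate(rows_channel),
            "value": np.round(np.concatenate(rows_value), 3),
        }
    )
    vitals = vitals.sort_values(
        ["subject_id", "channel", "time_hr"], kind="mergesort"
    ).reset_index(drop=True)
    vitals.insert(0, "obs_id", np.arange(len(vitals)))
    return vitals


def inject_missingness(
    vitals: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, MissingnessRecord]:
    """Delete subject-hour-channel cells independently at ``missing_rate`` and
    give selected subjects one contiguous run of >=5 missing hours on one channel.

    Returns the thinned table plus exact bookkeeping of every deleted cell so
    preprocessing exclusions can be verified against the injection record.
    """
    for rate in (config.missing_rate, config.long_gap_rate):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError("missingness rates must lie in [0, 1]")
    if config.missing_rate == 0.0 and config.long_gap_rate == 0.0:
        empty = pd.DataFrame(columns=["subject_id", "channel", "hour"])
        gaps = pd.DataFrame(columns=["subject_id", "channel", "start_hour", "length"])
        return vitals.copy(), MissingnessRecord(empty, gaps)

    rng = _rng(config.seed, 1)
    subjects = np.sort(vitals["subject_id"].unique())
    deleted = []

    # independent per-cell holes
    if config.missing_rate > 0.0:
        for ch in CHANNELS:
            drop = rng.random((len(subjects), 12)) < config.missing_rate
            sidx, hidx = np.nonzero(drop)
            deleted.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects[sidx],
                        "channel": ch,
                        "hour": hidx,
                    }
                )
            )

    # one long run (length 5 or 6) on one channel for selected subjects
    gap_rows = []
    hit = rng.random(len(subjects)) < config.long_gap_rate
    for sid in subjects[hit]:
        ch = CHANNELS[rng.integers(0, len(CHANNELS))]
        length = int(rng.integers(5, 7))
        start = int(rng.integers(0, 12 - length + 1))
        gap_rows.append((sid, ch, start, length))
        deleted.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "channel": ch,
                    "hour": np.arange(start, start + length),
                }
            )
        )
    gaps = pd.DataFrame(
        gap_rows, columns=["subject_id", "channel", "start_hour", "length"]
    )

    if deleted:
        cells = (
            pd.concat(deleted, ignore_index=True)
            .drop_duplicates()
            .sort_values(["subject_id", "channel", "hour"], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        cells = pd.DataFrame(columns=["subject_id", "channel", "hour"])

    out = vitals.copy()
    out["_hour"] = np.floor(out["time_hr"]).astype(int)
    key = pd.MultiIndex.from_frame(out[["subject_id", "channel", "_hour"]])
    bad = key.isin(pd.MultiIndex.from_frame(cells)) if len(cells) else np.zeros(len(out), bool)
    out = out.loc[~bad].drop(columns="_hour").reset_index(drop=True)
    return out, MissingnessRecord(cells, gaps)


def inject_outliers(
    vitals: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, OutlierRecord]:
    """Replace ``outlier_rate`` of observations with values strictly outside
    their channel's plausibility range; replaced positions are recorded."""
    if config.outlier_rate == 0.0 or vitals.empty:
        empty = pd.DataFrame(
            columns=["obs_id", "subject_id", "channel", "original", "injected"]
        )
        return vitals.copy(), OutlierRecord(empty)

    rng = _rng(config.seed, 2)
    out = vitals.copy().reset_index(drop=True)
    hit = np.nonzero(rng.random(len(out)) < config.outlier_rate)[0]
    injected = np.empty(len(hit))
    for j, i in enumerate(hit):
        lo, hi = config.plausibility.bounds(out.at[i, "channel"])
        span = hi - lo
        if rng.random() < 0.5:
            injected[j] = lo - span * rng.uniform(0.05, 0.5)
        else:
            injected[j] = hi + span * rng.uniform(0.05, 0.5)
    record = pd.DataFrame(
        {
            "obs_id": out.loc[hit, "obs_id"].to_numpy(),
            "subject_id": out.loc[hit, "subject_id"].to_numpy(),
            "channel": out.loc[hit, "channel"].to_numpy(),
            "original": out.loc[hit, "value"].to_numpy(),
            "injected": np.round(injected, 3),
        }
    )
    out.loc[hit, "value"] = np.round(injected, 3)
    return out, OutlierRecord(record)


def simulate(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth, MissingnessRecord, OutlierRecord]:
    """Full generator pass: cohort + vitals with holes and outliers injected."""
    vitals, cohort, truth = generate_cohort(config)
    vitals, missing_rec = inject_missingness(vitals, config)
    vitals, outlier_rec = inject_outliers(vitals, config)
    return vitals, cohort, truth, missing_rec, outlier_rec
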
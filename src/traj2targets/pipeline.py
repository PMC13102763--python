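"""End-to-end orchestration: simulate -> preprocess -> trajectory mixture ->
survival contrasts -> spline dose-response -> safe-zone targets.

All randomness flows from one root seed: stage s uses
``numpy.random.SeedSequence((root_seed, s))``, so two runs with the same
config are byte-identical.  The high-risk cluster is the one with the
highest ICU mortality among modal assignments; the reference cluster for
Cox contrasts is the one with the lowest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import traj2targets
from traj2targets.config import GAS_PARAMETERS, ConfigurationError, PipelineConfig
from traj2targets.gbmtm import (
    TrajectoryModelSpec,
    assign,
    backward_eliminate_orders,
    diagnostics,
    select_num_groups,
)
from traj2targets.preprocess import run_preprocess
from traj2targets.rcs import fit_rcs_cox, nonlinearity_report
from traj2targets.survival import adjusted_survival, cluster_contrast_table
from traj2targets.synthetic import default_scenario, simulate
from traj2targets.targets import RiskModelSpec, fit_all_targets, safe_zone_report

PROTECTED_COLUMNS = (
    "subject_id",
    "cluster",
    "time_icu",
    "event_icu",
    "time_28d",
    "event_28d",
    "time_90d",
    "event_90d",
    "time_365d",
    "event_365d",
)


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence((root, stage)).generate_state(1)[0] % (2**31 - 1))


def drop_sparse_columns(
    cohort: pd.DataFrame,
    threshold: float = 0.30,
    protected=PROTECTED_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove columns with a missing fraction strictly above ``threshold``.

    Protected columns (ids, outcomes, cluster) are never dropped; if one
    exceeds the threshold that is a hard error, not a silent removal.
    """
    frac = cohort.isna().mean()
    report = pd.DataFrame({"column": frac.index, "missing_fraction": frac.to_numpy()})
    to_drop = [c for c in cohort.columns if frac[c] > threshold]
    bad_protected = [c for c in to_drop if c in protected]
    if bad_protected:
        raise ConfigurationError(
            f"protected column(s) above missingness threshold: {bad_protected}"
        )
    report["dropped"] = report["column"].isin(to_drop)
    return cohort.drop(columns=to_drop), report


@dataclass
class RunManifest:
    config: dict
    root_seed: int
    stage_seeds: dict
    counts: dict
    input_hashes: dict
    version: str = traj2targets.__version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "root_seed": self.root_seed,
                "stage_seeds": self.stage_seeds,
                "counts": self.counts,
                "input_hashes": self.input_hashes,
                "version": self.version,
            },
            indent=1,
            default=str,
        )


@dataclass
class RunResult:
    manifest: RunManifest
    selection_table: pd.DataFrame
    posteriors: pd.DataFrame
    cluster_summary: pd.DataFrame
    cox_table: pd.DataFrame
    adjusted_curves: pd.DataFrame
    nonlinearity: pd.DataFrame
    pd_profiles: pd.DataFrame
    safe_zones: pd.DataFrame
    high_risk_cluster: int
    reference_cluster: int
    chosen_k: int
    fit_diagnostics: dict
    truth: object = None  # synthetic ground truth sidecar, never an input


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage on a synthetic cohort and collect the outputs."""
    root = config.seed

    # stage 0: synthetic cohort
    scen = default_scenario(n_subjects=config.n_subjects, seed=_stage_seed(root, 0))
    vitals, cohort, truth, missing_rec, outlier_rec = simulate(scen)

    # stage 1: preprocessing
    pre = run_preprocess(vitals)
    retained_ids = pre.grids.subject_ids

    # stage 2: sparse-column filter on the cohort table
    cohort, sparse_report = drop_sparse_columns(cohort, config.column_missing_threshold)

    # stage 3: trajectory mixture + model selection
    template = TrajectoryModelSpec(
        K=1,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol=config.tol,
        seed=_stage_seed(root, 3),
    )
    selection_table, chosen_k, fits = select_num_groups(
        pre.grids, k_range=config.k_range, template=template
    )
    if config.backward_eliminate and chosen_k > 1:
        _, fit = backward_eliminate_orders(
            pre.grids, chosen_k, template=template
        )
    else:
        fit = fits[chosen_k][0]
    diag = diagnostics(fit)
    labels = assign(fit.W)
    posteriors = pd.DataFrame(
        {"subject_id": retained_ids, "label": labels}
        | {f"w_{g + 1}": fit.W[:, g] for g in range(fit.K)}
    )

    # stage 4: survival records = cohort restricted to retained subjects + labels
    records = cohort[cohort["subject_id"].isin(retained_ids)].reset_index(drop=True)
    records = records.merge(posteriors[["subject_id", "label"]], on="subject_id")
    records = records.rename(columns={"label": "cluster"})

    icu_by_cluster = records.groupby("cluster")["event_icu"].mean()
    high_risk = int(icu_by_cluster.idxmax())
    reference = int(icu_by_cluster.idxmin())
    cluster_summary = (
        records.groupby("cluster")
        .agg(
            n=("subject_id", "size"),
            icu_mortality=("event_icu", "mean"),
            mortality_365d=("event_365d", "mean"),
        )
        .reset_index()
    )

    cox_table = cluster_contrast_table(
        records, horizons=config.horizons, reference_cluster=reference
    )
    curves = adjusted_survival(
        records,
        horizon="365d",
        reference_cluster=reference,
        n_boot=config.bootstrap_samples,
        seed=_stage_seed(root, 4),
    )
    adjusted_rows = []
    for g, c in curves.items():
        for t, s, lo, hi in zip(c.times, c.survival, c.lower, c.upper):
            adjusted_rows.append(
                {"cluster": g, "time": t, "survival": s, "lo": lo, "hi": hi}
            )
    adjusted_curves = pd.DataFrame(adjusted_rows)

    # stage 5: spline dose-response within the high-risk cluster
    high = records[records["cluster"] == high_risk].reset_index(drop=True)
    rcs_fits = {}
    for name in GAS_PARAMETERS:
        try:
            rcs_fits[name] = fit_rcs_cox(high, name, k=config.rcs_knots)
        except Exception as err:  # keep the report going; note the failure
            warnings.warn(f"RCS fit failed for {name}: {err}")
    nonlin = nonlinearity_report(rcs_fits)

    # stage 6: forests, partial dependence, safe zones
    rf_spec = RiskModelSpec(
        n_estimators=config.rf_n_estimators,
        min_samples_leaf=config.rf_min_samples_leaf,
        max_features=config.rf_max_features,
        cv_folds=config.cv_folds,
        seed=_stage_seed(root, 6),
    )
    profiles, zones, _ = fit_all_targets(
        high, rf_spec, delta=config.safe_zone_delta, grid_size=config.pd_grid_size
    )
    pd_rows = [
        {"parameter": name, "x": x, "pd": v}
        for name, prof in profiles.items()
        for x, v in zip(prof.grid, prof.values)
    ]
    pd_profiles = pd.DataFrame(pd_rows)
    zones_table = safe_zone_report(zones, n_used=len(high))

    excl_counts = (
        pre.exclusions["reason"].value_counts().to_dict() if len(pre.exclusions) else {}
    )
    counts = {
        "input_subjects": int(config.n_subjects),
        "retained_subjects": int(len(retained_ids)),
        "excluded_subjects": int(len(pre.exclusions)),
        "excluded_by_reason": excl_counts,
        "high_risk_cluster_n": int(len(high)),
    }
    assert counts["input_subjects"] == counts["retained_subjects"] + counts["excluded_subjects"]

    manifest = RunManifest(
        config=config.to_dict(),
        root_seed=root,
        stage_seeds={s: _stage_seed(root, s) for s in (0, 3, 4, 6)},
        counts=counts,
        input_hashes={"vitals": _hash_frame(vitals), "cohort": _hash_frame(cohort)},
    )
    result = RunResult(
        manifest=manifest,
        selection_table=selection_table,
        posteriors=posteriors,
        cluster_summary=cluster_summary,
        cox_table=cox_table,
        adjusted_curves=adjusted_curves,
        nonlinearity=nonlin,
        pd_profiles=pd_profiles,
        safe_zones=zones_table,
        high_risk_cluster=high_risk,
        reference_cluster=reference,
        chosen_k=chosen_k,
        fit_diagnostics={
            "entropy": diag.entropy,
            "bic": diag.bic,
            "aic": diag.aic,
            "group_sizes": diag.group_sizes.tolist(),
            "avepp": diag.avepp.tolist(),
            "occ": diag.occ.tolist(),
        },
        truth=truth,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: RunResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "selection_table.csv": result.selection_table,
        "posteriors.csv": result.posteriors,
        "cluster_summary.csv": result.cluster_summary,
        "cox_results.csv": result.cox_table,
        "adjusted_curves.csv": result.adjusted_curves,
        "nonlinearity.csv": result.nonlinearity,
        "pd_profiles.csv": result.pd_profiles,
        "safe_zones.csv": result.safe_zones,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    (out / "manifest.json").write_text(result.manifest.to_json())
    (out / "report.md").write_text(report(result))


def report(result: RunResult) -> str:
    """Human-readable run summary with every diagnostic threshold."""
    d = result.fit_diagnostics
    checks = [
        ("entropy > 0.7", d["entropy"] > 0.7, f"{d['entropy']:.3f}"),
        (
            "all AvePP > 0.7",
            bool(np.nanmin(d["avepp"]) > 0.7),
            f"min {np.nanmin(d['avepp']):.3f}",
        ),
        (
            "all OCC > 5",
            bool(np.nanmin(d["occ"]) > 5),
            f"min {np.nanmin(d['occ']):.2f}",
        ),
        (
            "all group shares >= 5%",
            bool(min(d["group_sizes"]) >= 0.05),
            f"min {min(d['group_sizes']):.3f}",
        ),
    ]
    lines = [
        "# Trajectory-to-targets run report",
        "",
        f"- subjects: {result.manifest.counts['input_subjects']} "
        f"(retained {result.manifest.counts['retained_subjects']}, "
        f"excluded {result.manifest.counts['excluded_subjects']})",
        f"- chosen number of trajectory groups: K = {result.chosen_k}",
        f"- high-risk cluster: {result.high_risk_cluster} "
        f"(reference: {result.reference_cluster})",
        "",
        "## Classification diagnostics",
        "",
        "| check | value | pass |",
        "|---|---|---|",
    ]
    for name, ok, val in checks:
        lines.append(f"| {name} | {val} | {'yes' if ok else 'NO'} |")
    lines += ["", "## Model selection", "", result.selection_table.round(3).to_markdown(index=False)]
    lines += ["", "## Cluster mortality", "", result.cluster_summary.round(3).to_markdown(index=False)]
    lines += ["", "## Hazard ratios (vs reference cluster)", "",
              result.cox_table.round(3).to_markdown(index=False)]
    lines += ["", "## Nonlinearity of blood gas dose-response", "",
              result.nonlinearity.round(4).to_markdown(index=False)]
    lines += ["", "## Safe zones", "",
              result.safe_zones.round(3).to_markdown(index=False), ""]
    return "\n".join(lines)
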
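"""Generate the synthetic ICU cohort the downstream analyses consume.

Writes vitals.csv (long-format raw observations with injected missingness
and outliers), cohort.csv (one row per subject: covariates, blood gases,
per-horizon survival) and truth.json (ground-truth labels and intervals,
kept out of all analysis inputs).
"""

import argparse
from pathlib import Path

from traj2targets.synthetic import default_scenario, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=2000, help="number of subjects")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    cfg = default_scenario(args.n, seed=args.seed)
    vitals, cohort, truth, missing_rec, outlier_rec = simulate(cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    vitals.to_csv(args.out / "vitals.csv", index=False)
    cohort.to_csv(args.out / "cohort.csv", index=False)
    (args.out / "truth.json").write_text(truth.to_json())
    missing_rec.long_gaps.to_csv(args.out / "injected_long_gaps.csv", index=False)

    print(f"subjects: {args.n}; vitals rows: {len(vitals)}")
    print(f"ICU mortality: {cohort['event_icu'].mean():.3f}")
    print(f"long-gap subjects injected: {missing_rec.long_gaps['subject_id'].nunique()}")
    print(f"outputs in {args.out}/")


if __name__ == "__main__":
    main()
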
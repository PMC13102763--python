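"""QC the raw vitals into complete standardized 6x12 hourly grids.

Order: plausibility filter -> winsorize -> hourly aggregate -> impute or
exclude (>4 consecutive missing hours) -> Z-score.  Writes grids.csv
(standardized long format), exclusions.csv and standardization.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from traj2targets.preprocess import run_preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--vitals", type=Path, default=Path("results/sim/vitals.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/preprocess"))
    args = ap.parse_args()

    vitals = pd.read_csv(args.vitals)
    res = run_preprocess(vitals)
    args.out.mkdir(parents=True, exist_ok=True)
    res.grids.to_long().to_csv(args.out / "grids.csv", index=False)
    res.exclusions.to_csv(args.out / "exclusions.csv", index=False)
    (args.out / "standardization.json").write_text(
        json.dumps(res.params.to_dict(), indent=1)
    )

    n_in = vitals["subject_id"].nunique()
    print(f"subjects in: {n_in}; retained: {res.n_retained}; excluded: {len(res.exclusions)}")
    if len(res.exclusions):
        print("exclusions by reason:", res.exclusions["reason"].value_counts().to_dict())
    print("implausible values removed per channel:", res.plausibility_report)


if __name__ == "__main__":
    main()
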
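#!/usr/bin/env python
"""PHO-promoter reporter induction and the study's group comparisons.

Builds a synthetic plate of prPHO5-yEGFP wells (wildtype and kcs1d, +Pi and
-Pi), normalizes per cell against blank wells, computes fold inductions,
and runs the Student/Tukey comparisons.  Writes tables under
results/reporter/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ippdyn import reporter_stats

OUT = Path("results/reporter")

# per-cell reporter output (a.u.) by strain x condition: the PHO5 promoter
# is off in replete wildtype, strongly induced on starvation, and
# constitutively on in kcs1d
TRUE_SIGNAL = {
    ("wt", "+Pi"): 1.0,
    ("wt", "-Pi"): 8.0,
    ("kcs1d", "+Pi"): 7.0,
    ("kcs1d", "-Pi"): 8.5,
}


def make_plate(seed: int = 0, n_wells: int = 6) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, condition), signal in TRUE_SIGNAL.items():
        for i in range(n_wells):
            cells = 1e7
            fluor = 100.0 + signal * 30.0 * cells / 1e7 * rng.normal(1.0, 0.08)
            rows.append((f"{strain}_{condition}_{i}", strain, condition, fluor, cells))
    for i in range(n_wells):
        rows.append((f"blank_{i}", "blank", "+Pi", rng.normal(100.0, 2.0), 1e7))
        rows.append((f"blank_-Pi_{i}", "blank", "-Pi", rng.normal(100.0, 2.0), 1e7))
    return pd.DataFrame(rows, columns=["well", "strain", "condition", "fluorescence", "cells"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    plate = make_plate()
    blanks = plate[plate["strain"] == "blank"]
    records = plate[plate["strain"] != "blank"]
    norm = reporter_stats.normalize_plate(records, blanks)
    norm.to_csv(OUT / "normalized.csv", index=False)

    print("Fold induction (-Pi / +Pi):")
    for strain in ("wt", "kcs1d"):
        sub = norm[norm["strain"] == strain]
        ratio = reporter_stats.induction_ratio(
            sub.loc[sub["condition"] == "-Pi", "norm_fluorescence"],
            sub.loc[sub["condition"] == "+Pi", "norm_fluorescence"],
        )
        print(f"  {strain}: {ratio:.1f}x")

    groups = {
        f"{strain} {cond}": grp["norm_fluorescence"].to_numpy()
        for (strain, cond), grp in norm.groupby(["strain", "condition"])
    }
    tukey = reporter_stats.compare_groups(groups, "tukey_hsd")
    tukey.to_csv(OUT / "tukey.csv", index=False)
    print("Tukey HSD (all pairs):")
    for _, row in tukey.iterrows():
        print(f"  {row['group1']} vs {row['group2']}: p = {row['pvalue']:.2e} {row['stars']}")


if __name__ == "__main__":
    main()
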
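"""Plate-reader reporter normalization and the group comparisons of the study.

Fluorescent PHO-promoter reporters (prPHO5-yEGFP, prPHO84-yEGFP) are read
on equal numbers of cells; raw fluorescence is blank-subtracted and
normalized per cell.  Group comparisons use two-sided Student's t,
Tukey's HSD (all pairs, family-wise corrected), or Mann-Whitney U, with
the conventional star coding (**** p<1e-4, *** p<1e-3, ** p<1e-2,
* p<0.05, n.s. otherwise).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_plate",
    "induction_ratio",
    "compare_groups",
    "p_to_stars",
]

METHODS = ("student_t", "tukey_hsd", "mann_whitney")


def p_to_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def normalize_plate(
    records: pd.DataFrame,
    blank_records: pd.DataFrame | None = None,
    dark_count: float | None = None,
) -> pd.DataFrame:
    """Blank-subtracted per-cell fluorescence.

    ``records`` needs columns ``fluorescence`` and ``cells``; blanks are
    matched per ``condition`` (and ``time_h``) when those columns exist in
    both tables, otherwise the grand blank mean is used.  With no blank
    wells, a ``dark_count`` constant must be supplied.  Negative
    normalized values are clipped to 0 and flagged.
    """
    df = records.copy()
    if (df["fluorescence"] < 0).any():
        raise ValueError("raw fluorescence must be >= 0")
    if (df["cells"] <= 0).any():
        raise ValueError("cell counts must be positive")

    if blank_records is None:
        if dark_count is None:
            raise ValueError("need blank wells or a dark-count constant")
        df["blank"] = float(dark_count)
    else:
        match_cols = [
            c for c in ("condition", "time_h")
            if c in df.columns and c in blank_records.columns
        ]
        if match_cols:
            blank_means = blank_records.groupby(match_cols)["fluorescence"].mean()
            keys = list(df[match_cols].itertuples(index=False, name=None))
            keys = [k[0] if len(match_cols) == 1 else k for k in keys]
            missing = [k for k in keys if k not in blank_means.index]
            if missing:
                raise ValueError(f"no blank wells for condition(s) {sorted(set(missing))}")
            df["blank"] = [float(blank_means.loc[k]) for k in keys]
        else:
            df["blank"] = float(blank_records["fluorescence"].mean())

    raw_norm = (df["fluorescence"] - df["blank"]) / df["cells"]
    df["clipped"] = raw_norm < 0
    df["norm_fluorescence"] = raw_norm.clip(lower=0.0)
    return df


def induction_ratio(starved, replete) -> float:
    """Fold induction: mean(-Pi) / mean(+Pi)."""
    s = float(np.mean(np.asarray(starved, dtype=float)))
    r = float(np.mean(np.asarray(replete, dtype=float)))
    if r <= 0:
        raise ValueError("replete mean must be positive")
    return s / r


def compare_groups(values_by_group: dict[str, np.ndarray], method: str) -> pd.DataFrame:
    """Two-sided group comparisons with star coding.

    ``student_t`` and ``mann_whitney`` test every pair independently;
    ``tukey_hsd`` tests all pairs with family-wise correction over the
    whole set of groups.  Returns one row per pair: group1, group2,
    statistic, pvalue, stars.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if method in ("student_t", "tukey_hsd"):
        for name, vals in groups.items():
            if vals.size < 2:
                raise ValueError(f"group {name!r} has n < 2")

    rows = []
    if method == "tukey_hsd":
        res = stats.tukey_hsd(*groups.values())
        for i, j in itertools.combinations(range(len(names)), 2):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "statistic": float(res.statistic[i, j]),
                    "pvalue": p,
                    "stars": p_to_stars(p),
                }
            )
    else:
        for a, b in itertools.combinations(names, 2):
            if method == "student_t":
                stat, p = stats.ttest_ind(groups[a], groups[b], equal_var=True)
            else:
                stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append(
                {
                    "group1": a,
                    "group2": b,
                    "statistic": float(stat),
                    "pvalue": float(p),
                    "stars": p_to_stars(float(p)),
                }
            )
    return pd.DataFrame(rows)
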
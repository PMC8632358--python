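"""Relative qPCR expression by the 2^-ddCt method.

Each sample's target-gene Ct is normalized against a reference gene
(dCt = Ct_target - Ct_reference, technical replicates averaged first),
then against the mean dCt of the control group (ddCt); the per-sample fold
change is 2^-ddCt.  Group folds are geometric means, folds being log-scale
quantities; per-sample folds are emitted so arithmetic summaries can be
recomputed.  Group comparison is a Welch t-test on the dCt scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "target_ct", "reference_ct"]
GROUPS = ("control", "treated")


@dataclass
class RelativeExpression:
    """Per-sample and per-group 2^-ddCt summaries."""

    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, fold
    group_fold: dict[str, float]  # geometric mean fold per group
    group_fold_sd: dict[str, float]  # SD of per-sample folds
    ddct_mean: dict[str, float]
    welch_t: float
    welch_p: float


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample_id, group, target_ct, reference_ct."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def delta_delta_ct(table: pd.DataFrame) -> RelativeExpression:
    """Compute relative expression from a Ct table.

    Technical replicates (rows sharing a sample_id) are averaged before any
    differencing.  ddCt is each sample's dCt minus the control-group mean
    dCt, so the control group's geometric-mean fold is exactly 1.
    """
    df = table.copy()
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}; "
                         f"expected {GROUPS}")
    if df[["target_ct", "reference_ct"]].isna().any().any():
        missing = df.loc[df[["target_ct", "reference_ct"]].isna().any(axis=1),
                         "sample_id"].tolist()
        raise ValueError(f"missing Ct values for samples {missing}")
    if (df[["target_ct", "reference_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")

    per = (df.groupby(["sample_id", "group"], as_index=False)
             [["target_ct", "reference_ct"]].mean())
    per["delta_ct"] = per["target_ct"] - per["reference_ct"]
    for g in GROUPS:
        if not (per["group"] == g).any():
            raise ValueError(f"no samples in group {g!r}")

    control_mean = per.loc[per["group"] == "control", "delta_ct"].mean()
    per["ddct"] = per["delta_ct"] - control_mean
    per["fold"] = 2.0 ** (-per["ddct"])

    group_fold = {}
    group_sd = {}
    ddct_mean = {}
    for g in GROUPS:
        folds = per.loc[per["group"] == g, "fold"]
        group_fold[g] = float(np.exp(np.mean(np.log(folds))))
        group_sd[g] = float(folds.std(ddof=1)) if len(folds) > 1 else 0.0
        ddct_mean[g] = float(per.loc[per["group"] == g, "ddct"].mean())

    dct_c = per.loc[per["group"] == "control", "delta_ct"]
    dct_t = per.loc[per["group"] == "treated", "delta_ct"]
    if len(dct_c) > 1 and len(dct_t) > 1:
        t, p = stats.ttest_ind(dct_t, dct_c, equal_var=False)
    else:
        t, p = float("nan"), float("nan")
    return RelativeExpression(
        per_sample=per[["sample_id", "group", "delta_ct", "ddct", "fold"]],
        group_fold=group_fold,
        group_fold_sd=group_sd,
        ddct_mean=ddct_mean,
        welch_t=float(t),
        welch_p=float(p),
    )


def write_fold_table(result: RelativeExpression, path: str | Path) -> Path:
    path = Path(path)
    result.per_sample.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
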
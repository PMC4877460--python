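"""Relative qPCR quantification: ΔCt, ΔΔCt and two-group tests.

Each well group is a triplicate of Ct values; the average Ct of the
triplicate is used throughout. Expression is normalized against a
reference gene (U6 by default): ``ΔCt = AvgCt_target - AvgCt_reference``,
contrasts use ``ΔΔCt = ΔCt_case - ΔCt_control`` and fold change
``2^(-ΔΔCt)``. Group comparisons are computed on ΔCt values with a Welch
t-test by default (pooled-variance and paired variants are available).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("sample_id", "group", "target_id")
CT_COLUMNS = ("ct_rep1", "ct_rep2", "ct_rep3")


def delta_ct(ct_target_replicates: Sequence[float], ct_reference_replicates: Sequence[float]) -> float:
    """ΔCt = mean(target triplicate) - mean(reference triplicate)."""
    target = np.asarray(ct_target_replicates, dtype=float)
    reference = np.asarray(ct_reference_replicates, dtype=float)
    target = target[~np.isnan(target)]
    reference = reference[~np.isnan(reference)]
    if target.size == 0 or reference.size == 0:
        raise ValueError("replicate sets must be non-empty")
    return float(target.mean() - reference.mean())


def ddct_fold_change(dct_case: float, dct_control: float) -> tuple[float, float]:
    """ΔΔCt and the corresponding fold change ``2^(-ΔΔCt)``.

    A negative ΔΔCt means the case expresses more than the control (one
    fewer cycle per doubling of input).
    """
    if not (np.isfinite(dct_case) and np.isfinite(dct_control)):
        raise ValueError("ΔCt inputs must be finite")
    ddct = float(dct_case) - float(dct_control)
    return ddct, float(2.0 ** (-ddct))


def two_group_test(
    group1: Sequence[float],
    group2: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
) -> float:
    """Two-sided t-test p-value between two groups of ΔCt values.

    Welch (unequal variance) by default; ``equal_var=True`` gives the
    pooled-variance Student test and ``paired=True`` the paired test
    (inputs aligned by position).
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate zero-variance case: identical means are indistinguishable
        return 1.0 if a.mean() == b.mean() else 0.0
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        result = stats.ttest_rel(a, b)
    else:
        result = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(result.pvalue)


def sample_delta_ct(
    table: pd.DataFrame, reference_id: str = "U6"
) -> pd.DataFrame:
    """Per-(sample, target) ΔCt from a long-format Ct table.

    The table needs columns sample_id, group, target_id and ct_rep1..3
    (missing replicates as NaN); every sample must carry a reference-gene
    row.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"qPCR table lacks column {col!r}")
    ct_cols = [c for c in CT_COLUMNS if c in table.columns]
    if not ct_cols:
        raise ValueError("qPCR table lacks ct_rep columns")
    values = table[ct_cols].to_numpy(dtype=float)
    if np.nanmin(values) <= 0 or np.nanmax(values) >= 45:
        raise ValueError("Ct values must lie in (0, 45)")
    reference = table[table["target_id"] == reference_id]
    if reference.empty:
        raise ValueError(f"no rows for reference gene {reference_id!r}")
    ref_by_sample = {
        row.sample_id: [getattr(row, c) for c in ct_cols]
        for row in reference.itertuples(index=False)
    }
    rows = []
    for row in table[table["target_id"] != reference_id].itertuples(index=False):
        if row.sample_id not in ref_by_sample:
            raise ValueError(f"sample {row.sample_id!r} lacks a reference row")
        dct = delta_ct(
            [getattr(row, c) for c in ct_cols], ref_by_sample[row.sample_id]
        )
        rows.append((row.sample_id, row.group, row.target_id, dct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "target_id", "delta_ct"])


def summarize_groups(dct: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n of ΔCt per (target, group)."""
    summary = (
        dct.groupby(["target_id", "group"], sort=True)["delta_ct"]
        .agg(mean_dct="mean", sd_dct=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return summary


def analyze_qpcr(
    table: pd.DataFrame,
    reference_id: str = "U6",
    control_group: str = "normal",
    paired: bool = False,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full qPCR analysis: ΔCt summaries and per-contrast ΔΔCt table.

    Returns ``(summary, contrasts)``: the summary mirrors a
    mean-ΔCt ± SD presentation per target and group; contrasts report
    ΔΔCt, fold change and the t-test p-value of every non-control group
    against ``control_group``, plus the pairwise contrast between the two
    non-control groups when present.
    """
    dct = sample_delta_ct(table, reference_id)
    summary = summarize_groups(dct)
    groups = [g for g in dct["group"].unique() if g != control_group]
    contrast_pairs = [(g, control_group) for g in groups]
    if len(groups) == 2:
        contrast_pairs.append((groups[1], groups[0]))
    rows = []
    for target, sub in dct.groupby("target_id", sort=True):
        by_group = {g: v["delta_ct"].to_numpy() for g, v in sub.groupby("group")}
        for case, control in contrast_pairs:
            if case not in by_group or control not in by_group:
                continue
            ddct, fold = ddct_fold_change(
                float(np.mean(by_group[case])), float(np.mean(by_group[control]))
            )
            p = two_group_test(
                by_group[case], by_group[control], paired=paired, equal_var=equal_var
            )
            rows.append((target, case, control, ddct, fold, p))
    contrasts = pd.DataFrame(
        rows,
        columns=["target_id", "case", "control", "ddct", "fold_change", "p_value"],
    )
    return summary, contrasts
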
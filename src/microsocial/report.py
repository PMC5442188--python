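"""Consortium ranking, function-group comparison, and fitness-function correlation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .growth import FitnessTable
from .social import LABEL_NEGATIVE, LABEL_NEUTRAL, LABEL_POSITIVE

GROUP_POS_NEUTRAL = "pos_neutral"
GROUP_NEGATIVE = "negative"
GROUP_MIXED = "mixed"
GROUP_UNLABELED = "unlabeled"

GROUP_TESTS = ("wilcoxon", "welch_t")


def rank_consortia(table: FitnessTable, condition: str, top: int = 10) -> pd.DataFrame:
    """Top consortia: highest mean generations, then lowest log-phase time.

    Negative mean n (an OD decline) is clipped to 0 for the sort key only;
    the reported column keeps the raw mean. Remaining ties break on the
    canonical consortium ID, so the ranking is a total order.
    """
    mean_n = table.consortium_means("n", condition)
    mean_k = table.consortium_means("k", condition)
    lpt = table.log_phase_means(condition)
    df = pd.DataFrame(
        {
            "consortium": mean_n.index,
            "mean_n": mean_n.to_numpy(),
            "mean_k": mean_k.reindex(mean_n.index).to_numpy(),
            "log_phase_time": lpt.reindex(mean_n.index).to_numpy(),
        }
    )
    df["_key_n"] = np.clip(df["mean_n"], 0, None)
    df = df.sort_values(
        ["_key_n", "log_phase_time", "consortium"], ascending=[False, True, True], kind="stable"
    ).drop(columns="_key_n")
    df = df.head(top).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def read_function_table(path: str | Path) -> pd.DataFrame:
    """Read a per-consortium function CSV (columns ``consortium,condition,value``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("consortium", "condition", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: function table missing column(s) {missing}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if not np.all(np.isfinite(df["value"])):
        raise ValueError(f"{path}: function values must be finite")
    return df[["consortium", "condition", "value"]]


def assign_groups(
    membership: Mapping[str, frozenset[str]], overall: Mapping[str, str]
) -> dict[str, str]:
    """Partition consortia by the overall social labels of their members.

    ``pos_neutral``: every member positive or neutral; ``negative``: every
    member negative; ``mixed``: both kinds present; ``unlabeled``: any member
    without a label. Each consortium lands in exactly one group.
    """
    groups = {}
    for cid, members in membership.items():
        labels = [overall.get(m) for m in members]
        if any(lbl is None for lbl in labels):
            groups[cid] = GROUP_UNLABELED
        elif all(lbl in (LABEL_POSITIVE, LABEL_NEUTRAL) for lbl in labels):
            groups[cid] = GROUP_POS_NEUTRAL
        elif all(lbl == LABEL_NEGATIVE for lbl in labels):
            groups[cid] = GROUP_NEGATIVE
        else:
            groups[cid] = GROUP_MIXED
    return groups


@dataclass
class GroupComparison:
    test: str
    n_pos_neutral: int
    n_negative: int
    median_pos_neutral: float
    median_negative: float
    fold_change: float  # median(pos/neutral) / median(negative)
    statistic: float
    p: float

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "n_pos_neutral": self.n_pos_neutral,
            "n_negative": self.n_negative,
            "median_pos_neutral": self.median_pos_neutral,
            "median_negative": self.median_negative,
            "fold_change": self.fold_change,
            "statistic": self.statistic,
            "p": self.p,
        }


def compare_function_groups(
    function: pd.DataFrame,
    overall: Mapping[str, str],
    membership: Mapping[str, frozenset[str]],
    condition: str | None = None,
    test: str = "wilcoxon",
) -> GroupComparison:
    """Compare community function between all-positive/neutral and all-negative consortia.

    Mixed and unlabeled consortia are excluded. The default test is the
    two-sided Wilcoxon rank-sum (the claim is about medians); ``welch_t``
    switches to an unequal-variance t-test.
    """
    if test not in GROUP_TESTS:
        raise ValueError(f"unknown group test {test!r}; choose from {GROUP_TESTS}")
    func = function if condition is None else function[function["condition"] == condition]
    values = func.groupby("consortium", sort=True)["value"].mean()
    groups = assign_groups(membership, overall)
    a = values[[cid for cid in values.index if groups.get(cid) == GROUP_POS_NEUTRAL]].to_numpy()
    b = values[[cid for cid in values.index if groups.get(cid) == GROUP_NEGATIVE]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "need >= 2 consortia per social group for the function comparison "
            f"(got {len(a)} all-positive/neutral, {len(b)} all-negative); "
            "check that overall labels cover the relevant strains"
        )
    if test == "wilcoxon":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=False)
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    fold = med_a / med_b if med_b != 0 else float("inf")
    return GroupComparison(test, len(a), len(b), med_a, med_b, float(fold), float(stat), float(p))


def correlate_fitness_function(
    table: FitnessTable,
    function: pd.DataFrame,
    condition: str,
) -> pd.DataFrame:
    """Pearson and Spearman correlation of mean fitness (n and k) with function."""
    func = function[function["condition"] == condition]
    values = func.groupby("consortium", sort=True)["value"].mean()
    rows = []
    for metric in ("n", "k"):
        means = table.consortium_means(metric, condition)
        shared = sorted(set(means.index) & set(values.index))
        if len(shared) < 3:
            raise ValueError(
                f"need >= 3 matched consortia to correlate (metric {metric!r}, condition {condition!r}); "
                f"got {len(shared)}"
            )
        x = means.loc[shared].to_numpy()
        y = values.loc[shared].to_numpy()
        pr, pp = stats.pearsonr(x, y)
        sr, sp = stats.spearmanr(x, y)
        rows.append((condition, metric, float(pr), float(pp), float(sr), float(sp), len(shared)))
    return pd.DataFrame(
        rows,
        columns=["condition", "metric", "pearson_r", "pearson_p", "spearman_rho", "spearman_p", "n"],
    )
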
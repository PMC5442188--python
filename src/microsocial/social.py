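"""Net social behavior of strains from presence/absence fitness partitions.

For a focal strain the relative fitness of every consortium is its mean
fitness (number of generations n, or growth rate k) divided by the focal
strain's monoculture mean fitness. Three data sets are formed:

* ``w_a``  — all consortia,
* ``w_p``  — consortia containing the focal strain,
* ``w_np`` — consortia without it.

A Welch two-sample t-test compares w_p against w_np and the strain is called

* **positive** when the difference is significant and mean(w_p) > mean(w_np),
* **negative** when the difference is significant and mean(w_p) < mean(w_np),
  *or* when all three means exceed 1 (a strain that always benefits from the
  presence of others is a net taker regardless of the pairwise test),
* **neutral** otherwise.

Per-strain calls across conditions and metrics are joined pessimistically:
a strain negative in any data set is negative overall; otherwise positive in
any; otherwise neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import FitnessTable
from .plate_io import canonical_id

LABEL_POSITIVE = "positive"
LABEL_NEUTRAL = "neutral"
LABEL_NEGATIVE = "negative"

#: monoculture mean fitness below this is refused as a normalization constant
DENOMINATOR_FLOOR = 1e-6


@dataclass
class RelativeFitnessSet:
    """Relative fitness of every consortium for one focal strain and slice."""

    focal: str
    condition: str
    metric: str
    w_a: pd.Series  # indexed by canonical consortium ID
    w_p: pd.Series
    w_np: pd.Series
    denominator: float
    n_missing: int = 0


@dataclass
class SocialCall:
    focal: str
    condition: str
    metric: str
    label: str
    mean_wp: float
    mean_wnp: float
    mean_wa: float
    t: float
    p: float
    all_means_gt1: bool
    degenerate: bool = False


def relative_fitness(
    table: FitnessTable,
    focal: str,
    condition: str,
    metric: str,
    exclude_monocultures: bool = False,
) -> RelativeFitnessSet:
    """Eq.-style relative fitness sets w_a / w_p / w_np for one focal strain.

    The default includes every consortium of the design (the focal
    monoculture contributes w = 1 to w_p exactly); ``exclude_monocultures``
    restricts the analysis to mixed communities only.
    """
    if focal not in table.panel:
        raise KeyError(f"focal strain {focal!r} not in panel")
    means = table.consortium_means(metric, condition)
    mono_id = canonical_id([focal])
    if mono_id not in means.index:
        raise ValueError(f"monoculture of {focal!r} absent from fitness table ({condition}, {metric})")
    denominator = float(means[mono_id])
    if denominator <= DENOMINATOR_FLOOR:
        raise ValueError(
            f"undefined normalization: monoculture {metric}-fitness of strain {focal!r} "
            f"is {denominator:.3g} <= {DENOMINATOR_FLOOR:g}"
        )
    if exclude_monocultures:
        keep = [cid for cid in means.index if len(table.membership[cid]) > 1]
        means = means.loc[keep]
    w_a = means / denominator
    present = np.array([focal in table.membership[cid] for cid in w_a.index])
    n_missing = sum(1 for cell in table.missing if cell[1] == condition)
    return RelativeFitnessSet(
        focal=focal,
        condition=condition,
        metric=metric,
        w_a=w_a,
        w_p=w_a[present],
        w_np=w_a[~present],
        denominator=denominator,
        n_missing=n_missing,
    )


def classify_social(rfs: RelativeFitnessSet, alpha: float = 0.05) -> SocialCall:
    """Label one focal strain from its relative-fitness partition.

    Decision rule (in order):

    1. both groups constant -> neutral with t = 0, p = 1, flagged degenerate;
    2. negative when all of mean(w_a), mean(w_np), mean(w_p) > 1, or the
       Welch test is significant with mean(w_p) < mean(w_np);
    3. positive when the Welch test is significant with mean(w_p) > mean(w_np);
    4. neutral otherwise.
    """
    wp = rfs.w_p.to_numpy(dtype=float)
    wnp = rfs.w_np.to_numpy(dtype=float)
    if len(wp) < 2 or len(wnp) < 2:
        raise ValueError(
            f"strain {rfs.focal!r}: need >= 2 consortia in each partition "
            f"(got |w_p|={len(wp)}, |w_np|={len(wnp)})"
        )
    mean_wp = float(wp.mean())
    mean_wnp = float(wnp.mean())
    mean_wa = float(rfs.w_a.mean())
    all_gt1 = mean_wa > 1 and mean_wnp > 1 and mean_wp > 1
    # values identical in both groups (up to float round-off) carry no signal
    tol = 1e-12 * max(1.0, abs(mean_wp), abs(mean_wnp))
    degenerate = np.ptp(wp) <= tol and np.ptp(wnp) <= tol
    if degenerate:
        t_stat, p_val = 0.0, 1.0
        label = LABEL_NEUTRAL
    else:
        t_stat, p_val = stats.ttest_ind(wp, wnp, equal_var=False)
        t_stat, p_val = float(t_stat), float(p_val)
        if all_gt1 or (p_val < alpha and mean_wp < mean_wnp):
            label = LABEL_NEGATIVE
        elif p_val < alpha and mean_wp > mean_wnp:
            label = LABEL_POSITIVE
        else:
            label = LABEL_NEUTRAL
    return SocialCall(
        focal=rfs.focal,
        condition=rfs.condition,
        metric=rfs.metric,
        label=label,
        mean_wp=mean_wp,
        mean_wnp=mean_wnp,
        mean_wa=mean_wa,
        t=t_stat,
        p=p_val,
        all_means_gt1=all_gt1,
        degenerate=degenerate,
    )


def classify_panel(
    table: FitnessTable,
    alpha: float = 0.05,
    exclude_monocultures: bool = False,
    metrics: Sequence[str] = ("n", "k"),
) -> list[SocialCall]:
    """One SocialCall per (strain, condition, metric), deterministic order."""
    calls = []
    for condition in table.conditions:
        for metric in metrics:
            for strain in table.panel:
                rfs = relative_fitness(
                    table, strain, condition, metric, exclude_monocultures=exclude_monocultures
                )
                calls.append(classify_social(rfs, alpha=alpha))
    return calls


def aggregate_calls(calls: Iterable[SocialCall]) -> dict[str, str]:
    """Overall label per strain: negative if negative anywhere, else positive
    if positive anywhere, else neutral."""
    by_strain: dict[str, list[str]] = {}
    for call in calls:
        by_strain.setdefault(call.focal, []).append(call.label)
    out = {}
    for strain in sorted(by_strain):
        labels = by_strain[strain]
        if LABEL_NEGATIVE in labels:
            out[strain] = LABEL_NEGATIVE
        elif LABEL_POSITIVE in labels:
            out[strain] = LABEL_POSITIVE
        else:
            out[strain] = LABEL_NEUTRAL
    return out


def calls_to_frame(calls: Iterable[SocialCall]) -> pd.DataFrame:
    rows = [
        (
            c.focal,
            c.condition,
            c.metric,
            c.label,
            c.mean_wp,
            c.mean_wnp,
            c.mean_wa,
            c.t,
            c.p,
            c.all_means_gt1,
            c.degenerate,
        )
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "strain",
            "condition",
            "metric",
            "label",
            "mean_wp",
            "mean_wnp",
            "mean_wa",
            "t",
            "p",
            "all_means_gt1",
            "degenerate",
        ],
    )
    return df.sort_values(["strain", "condition", "metric"], kind="stable").reset_index(drop=True)


def overall_to_frame(overall: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(sorted(overall.items()), columns=["strain", "label"])
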
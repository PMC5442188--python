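"""Species richness versus fitness and stability.

Three analyses over the full combinatorial design:

* **richness_fitness** — consortia grouped by richness r (group sizes follow
  C(N, r): 7/21/35/35/21/7/1 for N = 7), fitness normalized by the single
  fittest monoculture, so any value > 1 beats the best individual strain.
* **cumulative_best** — strains ranked by monoculture fitness; for each m the
  group holds *all* subsets of the top-m strains (sizes 2^m - 1:
  1/3/7/15/31/63/127), again normalized by the fittest monoculture. Consortia
  exceeding 1 are tabulated.
* **cv_stability** — the coefficient of variation (sample sd / mean over
  replicates) per consortium as an inverse stability index, with per-richness
  medians and ordinary least-squares regressions of CV (and, optionally, of a
  measured community function) on richness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import FitnessTable

logger = logging.getLogger(__name__)


@dataclass
class RichnessSummary:
    metric: str
    condition: str
    groups: dict[int, pd.Series]  # richness -> normalized values (indexed by consortium)
    counts: dict[int, int]
    normalizer: float
    benchmark_strain: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.groups):
            for cid, v in self.groups[r].items():
                rows.append((self.condition, self.metric, r, cid, v))
        return pd.DataFrame(rows, columns=["condition", "metric", "richness", "consortium", "normalized_fitness"])


@dataclass
class CumulativeBestSummary:
    metric: str
    condition: str
    ranking: list[str]  # strains, fittest first
    sets: dict[int, list[str]]  # m -> canonical consortium IDs (all subsets of top-m)
    values: dict[int, pd.Series]
    counts: dict[int, int]
    normalizer: float
    gt1: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.sets):
            for cid in self.sets[m]:
                rows.append((self.condition, self.metric, m, cid, self.values[m][cid]))
        return pd.DataFrame(rows, columns=["condition", "metric", "n_best", "consortium", "normalized_fitness"])


@dataclass
class StabilityResult:
    per_consortium: pd.DataFrame  # consortium, condition, metric, richness, cv
    per_richness: pd.DataFrame  # condition, metric, richness, median_cv
    regressions: pd.DataFrame  # condition, metric, basis, slope, intercept, r2, p
    function_regressions: pd.DataFrame | None = None


def _normalizer(table: FitnessTable, metric: str, condition: str) -> tuple[str, float]:
    monos = table.monoculture_means(metric, condition)
    if monos.empty:
        raise ValueError(f"no monocultures in fitness table ({condition}, {metric})")
    best = float(monos.max())
    if best <= 0:
        raise ValueError(
            f"all monoculture {metric}-fitness values are <= 0 under {condition}; cannot normalize"
        )
    # deterministic tie-break: lexicographically smallest strain among the maxima
    benchmark = sorted(monos.index[monos == monos.max()])[0]
    return benchmark, best


def richness_fitness(table: FitnessTable, metric: str, condition: str) -> RichnessSummary:
    """Normalized consortium fitness grouped by species richness."""
    benchmark, norm = _normalizer(table, metric, condition)
    means = table.consortium_means(metric, condition)
    groups: dict[int, pd.Series] = {}
    for cid, value in means.items():
        r = table.richness_of(cid)
        groups.setdefault(r, {})[cid] = value / norm
    groups = {r: pd.Series(vals).sort_index() for r, vals in sorted(groups.items())}
    counts = {r: len(vals) for r, vals in groups.items()}
    return RichnessSummary(metric, condition, groups, counts, norm, benchmark)


def rank_strains(table: FitnessTable, metric: str, condition: str) -> list[str]:
    """Strains ordered fittest -> weakest by monoculture mean fitness.

    Ties are broken lexicographically by strain ID (deterministic).
    """
    monos = table.monoculture_means(metric, condition)
    return sorted(monos.index, key=lambda s: (-monos[s], s))


def cumulative_best(table: FitnessTable, metric: str, condition: str) -> CumulativeBestSummary:
    """All combinations of the m fittest strains, for m = 1..N, normalized."""
    benchmark, norm = _normalizer(table, metric, condition)
    means = table.consortium_means(metric, condition)
    ranking = rank_strains(table, metric, condition)
    sets: dict[int, list[str]] = {}
    values: dict[int, pd.Series] = {}
    gt1_rows = []
    for m in range(1, len(ranking) + 1):
        top = set(ranking[:m])
        cids = sorted(
            (cid for cid in means.index if table.membership[cid] <= top),
            key=lambda cid: (len(table.membership[cid]), cid),
        )
        vals = means.loc[cids] / norm
        sets[m] = cids
        values[m] = vals
        for cid, v in vals.items():
            if v > 1:
                gt1_rows.append((condition, metric, m, cid, v))
    gt1 = pd.DataFrame(gt1_rows, columns=["condition", "metric", "n_best", "consortium", "normalized_fitness"])
    counts = {m: len(cids) for m, cids in sets.items()}
    return CumulativeBestSummary(metric, condition, ranking, sets, values, counts, norm, gt1)


def cv_stability(table: FitnessTable, function_table: pd.DataFrame | None = None) -> StabilityResult:
    """Coefficient of variation across replicates versus species richness.

    CV uses the sample standard deviation (ddof = 1). Consortia whose
    replicate mean is <= 0 have an undefined CV and are excluded with a
    warning. Regressions are reported both on per-richness medians and on all
    per-consortium points; if ``function_table`` (columns ``consortium,
    condition, value``) is given, its values are regressed on richness too.
    """
    rows = []
    excluded = []
    for (cid, condition, metric), grp in table.data.groupby(["consortium", "condition", "metric"], sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"consortium {cid!r} ({condition}, {metric}): need >= 2 replicates for CV")
        mean = vals.mean()
        if mean <= 0:
            excluded.append((cid, condition, metric))
            continue
        cv = vals.std(ddof=1) / mean
        rows.append((cid, condition, metric, table.richness_of(cid), cv))
    if excluded:
        logger.warning("CV undefined (non-positive mean) for %d consortium slice(s): %s", len(excluded), excluded[:5])
    per_consortium = pd.DataFrame(rows, columns=["consortium", "condition", "metric", "richness", "cv"])
    per_richness = (
        per_consortium.groupby(["condition", "metric", "richness"], sort=True)["cv"]
        .median()
        .rename("median_cv")
        .reset_index()
    )
    reg_rows = []
    for (condition, metric), grp in per_consortium.groupby(["condition", "metric"], sort=True):
        med = per_richness[(per_richness["condition"] == condition) & (per_richness["metric"] == metric)]
        for basis, x, y in (
            ("median", med["richness"], med["median_cv"]),
            ("all", grp["richness"], grp["cv"]),
        ):
            if x.nunique() < 2:
                continue
            fit = stats.linregress(x, y)
            reg_rows.append((condition, metric, basis, fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue))
    regressions = pd.DataFrame(
        reg_rows, columns=["condition", "metric", "basis", "slope", "intercept", "r2", "p"]
    )

    function_regressions = None
    if function_table is not None:
        frows = []
        func = function_table.copy()
        func["richness"] = [table.richness_of(cid) for cid in func["consortium"]]
        for condition, grp in func.groupby("condition", sort=True):
            med = grp.groupby("richness")["value"].median()
            for basis, x, y in (("median", med.index, med.to_numpy()), ("all", grp["richness"], grp["value"])):
                if pd.Series(x).nunique() < 2:
                    continue
                fit = stats.linregress(x, y)
                frows.append((condition, basis, fit.slope, fit.intercept, fit.rvalue**2, fit.pvalue))
        function_regressions = pd.DataFrame(
            frows, columns=["condition", "basis", "slope", "intercept", "r2", "p"]
        )
    return StabilityResult(per_consortium, per_richness, regressions, function_regressions)
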
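"""Growth-curve feature extraction and the per-consortium fitness table.

Fitness of a consortium is summarized by two interval-based quantities taken
from its OD curve:

* number of generations ``n = (log b - log B) / log 2`` where ``B`` and ``b``
  are the (baseline-corrected) ODs at the start and end of the detected
  log-phase window, and
* growth rate ``k`` — generations per hour — the least-squares slope of
  log2(corrected OD) versus time over that window.

The log-phase window itself is detected with a parameter-light slope
threshold rule: pointwise slopes of log2(corrected OD) are estimated by
least squares over a centered sliding window of readings (3 readings
reproduces the classic centered difference; the default of 7 suppresses the
slope noise that plate-reader error injects at a 1 h cadence), and the
window is the maximal contiguous run of slopes >= theta * (maximum slope)
that contains the maximum-slope point. On a clean exponential every slope
equals the true rate, the run covers the full span, and both n and k are
recovered exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .plate_io import ODTimeSeries, PlateLayout, StrainPanel, canonical_id

logger = logging.getLogger(__name__)

METRICS = ("n", "k")

#: feature-status values
STATUS_OK = "ok"
STATUS_NO_GROWTH = "no-growth"
STATUS_MISSING = "missing"


@dataclass(frozen=True)
class GrowthConfig:
    """Tunable knobs of the extraction rule.

    baseline_points
        number of initial readings whose minimum is taken as the well blank.
    baseline_floor
        OD added back after blank subtraction so logarithms stay defined
        (corrected values are clipped to this floor).
    theta
        slope threshold as a fraction of the maximum pointwise slope; the
        log-phase window is the contiguous run of slopes >= theta * max.
    no_growth_delta
        a well whose corrected OD never rises this far above the floor is
        reported as "no-growth" with n = k = 0.
    slope_points
        width (odd number of readings) of the centered least-squares window
        used for pointwise slopes; 3 is the classic centered difference.
    """

    baseline_points: int = 3
    baseline_floor: float = 0.01
    theta: float = 0.5
    no_growth_delta: float = 0.02
    slope_points: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.baseline_floor <= 0:
            raise ValueError("baseline_floor must be positive")
        if self.baseline_points < 1:
            raise ValueError("baseline_points must be >= 1")
        if self.slope_points < 3 or self.slope_points % 2 == 0:
            raise ValueError("slope_points must be an odd integer >= 3")


DEFAULT_CONFIG = GrowthConfig()


@dataclass
class GrowthFeatures:
    """Per-well growth summary over the detected log-phase window."""

    well: str
    B: float
    b: float
    n: float
    k: float
    log_phase_start: float
    log_phase_end: float
    status: str = STATUS_OK

    @property
    def log_phase_time(self) -> float:
        return self.log_phase_end - self.log_phase_start


def compute_generations(B, b):
    """Number of generations between OD endpoints: (log b - log B) / log 2.

    Negative values (a declining interval) are returned as-is; callers flag
    them. Non-positive endpoints are a domain error.
    """
    B = np.asarray(B, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(B <= 0) or np.any(b <= 0):
        raise ValueError("OD endpoints must be positive (logarithm undefined)")
    n = (np.log(b) - np.log(B)) / math.log(2)
    return float(n) if n.ndim == 0 else n


def baseline_correct(od: np.ndarray, config: GrowthConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Subtract the minimum of the first readings, add the floor, clip at the floor."""
    od = np.asarray(od, dtype=float)
    blank = od[: config.baseline_points].min()
    return np.maximum(od - blank + config.baseline_floor, config.baseline_floor)


def _pointwise_slopes(times: np.ndarray, y: np.ndarray, points: int = 7) -> np.ndarray:
    """Least-squares slope of y(t) in a centered window of ``points`` readings.

    Windows are clipped (hence shrunk) at the series boundaries; ``points=3``
    on a uniform grid is exactly the centered finite difference.
    """
    n = len(times)
    half = min(points, n if n % 2 else n - 1) // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)

    def cum(a: np.ndarray) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(a)))

    st, st2 = cum(times), cum(times * times)
    sy, sty = cum(y), cum(times * y)
    m = (hi - lo + 1).astype(float)
    s_t = st[hi + 1] - st[lo]
    s_t2 = st2[hi + 1] - st2[lo]
    s_y = sy[hi + 1] - sy[lo]
    s_ty = sty[hi + 1] - sty[lo]
    denom = s_t2 - s_t * s_t / m
    return (s_ty - s_t * s_y / m) / denom


def _log_phase_indices(
    times: np.ndarray, corrected: np.ndarray, config: GrowthConfig
) -> tuple[int, int, str]:
    if corrected.max() - config.baseline_floor < config.no_growth_delta:
        return 0, 0, STATUS_NO_GROWTH
    y = np.log2(corrected)
    slopes = _pointwise_slopes(times, y, config.slope_points)
    imax = int(np.argmax(slopes))
    if slopes[imax] <= 0:
        return 0, 0, STATUS_NO_GROWTH
    threshold = config.theta * slopes[imax]
    lo = hi = imax
    while lo > 0 and slopes[lo - 1] >= threshold:
        lo -= 1
    while hi < len(slopes) - 1 and slopes[hi + 1] >= threshold:
        hi += 1
    if hi == lo:  # degenerate single-point run: extend toward the steeper neighbor
        if lo == 0:
            hi += 1
        elif hi == len(slopes) - 1:
            lo -= 1
        elif slopes[hi + 1] >= slopes[lo - 1]:
            hi += 1
        else:
            lo -= 1
    return lo, hi, STATUS_OK


def detect_log_phase(
    curve: ODTimeSeries, config: GrowthConfig = DEFAULT_CONFIG
) -> tuple[float, float, float, float]:
    """Detected log-phase window as (start_time, end_time, B, b).

    Flat / all-below-floor curves return a degenerate zero-length window at
    the first time point rather than raising.
    """
    corrected = baseline_correct(curve.od, config)
    lo, hi, status = _log_phase_indices(curve.times, corrected, config)
    if status == STATUS_NO_GROWTH:
        t0 = float(curve.times[0])
        return t0, t0, float(corrected[0]), float(corrected[0])
    return float(curve.times[lo]), float(curve.times[hi]), float(corrected[lo]), float(corrected[hi])


def compute_growth_rate(
    curve: ODTimeSeries,
    window: tuple[float, float],
    config: GrowthConfig = DEFAULT_CONFIG,
) -> float:
    """Least-squares slope of log2(corrected OD) vs time over the window (gen/h)."""
    start, end = window
    corrected = baseline_correct(curve.od, config)
    mask = (curve.times >= start) & (curve.times <= end)
    if mask.sum() < 2:
        raise ValueError(f"well {curve.well!r}: log-phase window [{start}, {end}] has < 2 points")
    slope, _ = np.polyfit(curve.times[mask], np.log2(corrected[mask]), 1)
    return float(slope)


def extract_features(curve: ODTimeSeries, config: GrowthConfig = DEFAULT_CONFIG) -> GrowthFeatures:
    """Full per-well extraction: window, endpoints, n and k."""
    corrected = baseline_correct(curve.od, config)
    lo, hi, status = _log_phase_indices(curve.times, corrected, config)
    if status == STATUS_NO_GROWTH:
        t0 = float(curve.times[0])
        od0 = float(corrected[0])
        return GrowthFeatures(curve.well, od0, od0, 0.0, 0.0, t0, t0, STATUS_NO_GROWTH)
    B = float(corrected[lo])
    b = float(corrected[hi])
    n = compute_generations(B, b)
    slope, _ = np.polyfit(curve.times[lo : hi + 1], np.log2(corrected[lo : hi + 1]), 1)
    return GrowthFeatures(
        curve.well, B, b, n, float(slope), float(curve.times[lo]), float(curve.times[hi]), STATUS_OK
    )


def extract_all(
    series: Mapping[str, ODTimeSeries], config: GrowthConfig = DEFAULT_CONFIG
) -> dict[str, GrowthFeatures]:
    return {well: extract_features(ts, config) for well, ts in series.items()}


class FitnessTable:
    """Replicate-level fitness values with consortium membership attached.

    ``data`` is a long table with one row per (consortium, condition,
    replicate, metric): columns ``consortium, condition, replicate, metric,
    value, log_phase_time, status``. Summaries (mean, sd) are arithmetic over
    replicate values, matching the use of consortium means downstream.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        membership: Mapping[str, frozenset[str]],
        panel: StrainPanel,
        missing: list[tuple[str, str]] | None = None,
    ) -> None:
        required = {"consortium", "condition", "replicate", "metric", "value", "log_phase_time", "status"}
        if not required.issubset(data.columns):
            raise ValueError(f"fitness data missing columns {sorted(required - set(data.columns))}")
        self.data = data.sort_values(["condition", "consortium", "metric", "replicate"], kind="stable").reset_index(
            drop=True
        )
        self.membership = dict(membership)
        self.panel = panel
        self.missing = list(missing or [])

    # -- accessors ---------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def richness_of(self, consortium: str) -> int:
        return len(self.membership[consortium])

    def summary(self) -> pd.DataFrame:
        """Per (consortium, condition, metric): mean, sd, replicate count, status."""
        grp = self.data.groupby(["consortium", "condition", "metric"], sort=True)
        out = grp.agg(
            mean=("value", "mean"),
            sd=("value", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n_reps=("value", "size"),
            log_phase_time=("log_phase_time", "mean"),
            status=("status", lambda s: STATUS_OK if (s == STATUS_OK).all() else ";".join(sorted(set(s) - {STATUS_OK}))),
        ).reset_index()
        return out

    def consortium_means(self, metric: str, condition: str) -> pd.Series:
        """Mean fitness per consortium for one (metric, condition) slice."""
        sel = self.data[(self.data["metric"] == metric) & (self.data["condition"] == condition)]
        if sel.empty:
            raise KeyError(f"no fitness rows for metric={metric!r}, condition={condition!r}")
        return sel.groupby("consortium", sort=True)["value"].mean()

    def replicate_values(self, metric: str, condition: str) -> pd.DataFrame:
        return self.data[(self.data["metric"] == metric) & (self.data["condition"] == condition)]

    def monoculture_means(self, metric: str, condition: str) -> pd.Series:
        """Mean fitness of each single-strain consortium, indexed by strain ID."""
        means = self.consortium_means(metric, condition)
        rows = {}
        for cid, members in self.membership.items():
            if len(members) == 1 and cid in means.index:
                rows[next(iter(members))] = means[cid]
        return pd.Series(rows).sort_index()

    def log_phase_means(self, condition: str) -> pd.Series:
        sel = self.data[(self.data["condition"] == condition) & (self.data["metric"] == "n")]
        return sel.groupby("consortium", sort=True)["log_phase_time"].mean()

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide per-(consortium, condition, metric) table: rep1..repR, mean, sd, ..."""
        reps = self.data.pivot_table(
            index=["consortium", "condition", "metric"],
            columns="replicate",
            values="value",
            aggfunc="first",
        )
        reps.columns = [f"rep{int(c)}" for c in reps.columns]
        out = reps.reset_index().merge(self.summary(), on=["consortium", "condition", "metric"])
        return out.sort_values(["condition", "metric", "consortium"], kind="stable").reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_fitness_table(
    features: Mapping[str, GrowthFeatures],
    layout: PlateLayout,
) -> FitnessTable:
    """Group per-well features by (consortium, condition) into a FitnessTable.

    Wells absent from ``features`` are dropped; a (consortium, condition)
    cell that loses *all* replicates is flagged missing, excluded from the
    table, and reported with a warning.
    """
    rows = []
    lost_wells = []
    seen: set[tuple[str, str]] = set()
    for rec in layout.rows.itertuples(index=False):
        feat = features.get(rec.well)
        if feat is None:
            lost_wells.append(rec.well)
            continue
        seen.add((rec.consortium, rec.condition))
        for metric, value in (("n", feat.n), ("k", feat.k)):
            rows.append(
                (rec.consortium, rec.condition, int(rec.replicate), metric, value, feat.log_phase_time, feat.status)
            )
    if lost_wells:
        logger.warning("no growth features for %d layout well(s): %s", len(lost_wells), lost_wells[:10])
    expected = {(rec.consortium, rec.condition) for rec in layout.rows.itertuples(index=False)}
    missing = sorted(expected - seen)
    if missing:
        logger.warning(
            "%d (consortium, condition) cell(s) have zero successful replicates and are excluded: %s",
            len(missing),
            missing[:10],
        )
    data = pd.DataFrame(
        rows, columns=["consortium", "condition", "replicate", "metric", "value", "log_phase_time", "status"]
    )
    if data.empty:
        raise ValueError("no usable wells: cannot build a fitness table")
    return FitnessTable(data, layout.membership, layout.panel, missing)
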
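"""End-to-end orchestration: inputs -> fitness -> social -> diversity -> phylo -> report.

Outputs are plain TSV/JSON with floats at 6 significant digits so re-running
with an identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import cumulative_best, cv_stability, richness_fitness
from .growth import GrowthConfig, build_fitness_table, extract_all
from .phylo import StrainTree, adonis, patristic_fitness_regression, unifrac_matrix
from .plate_io import StrainPanel, read_od_timeseries, read_plate_layout
from .report import (
    GROUP_TESTS,
    compare_function_groups,
    correlate_fitness_function,
    rank_consortia,
    read_function_table,
)
from .social import aggregate_calls, calls_to_frame, classify_panel, overall_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run."""

    layout: Path
    od: Path
    out: Path
    function: Path | None = None
    tree: Path | None = None
    panel: StrainPanel | None = None  # inferred from the layout file when absent
    alpha: float = 0.05
    theta: float = 0.5
    n_perm: int = 999
    seed: int = 0
    exclude_monocultures: bool = False
    group_test: str = "wilcoxon"
    phylo_metric: str = "n"
    phylo_condition: str | None = None
    top: int = 10

    def __post_init__(self) -> None:
        self.layout = Path(self.layout)
        self.od = Path(self.od)
        self.out = Path(self.out)
        self.function = Path(self.function) if self.function else None
        self.tree = Path(self.tree) if self.tree else None
        for path in (self.layout, self.od, self.function, self.tree):
            if path is not None and not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
        if self.group_test not in GROUP_TESTS:
            raise ValueError(f"group_test must be one of {GROUP_TESTS}")

    def echo(self) -> dict:
        return {
            "layout": str(self.layout),
            "od": str(self.od),
            "function": str(self.function) if self.function else None,
            "tree": str(self.tree) if self.tree else None,
            "out": str(self.out),
            "alpha": self.alpha,
            "theta": self.theta,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "exclude_monocultures": self.exclude_monocultures,
            "group_test": self.group_test,
            "phylo_metric": self.phylo_metric,
            "phylo_condition": self.phylo_condition,
            "top": self.top,
        }


def _round_floats(obj, digits: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def infer_panel(layout_path: Path) -> StrainPanel:
    """Panel = sorted union of strains named in the layout file."""
    df = pd.read_csv(layout_path, dtype=str)
    if "strains" not in df.columns:
        raise ValueError(f"{layout_path}: no 'strains' column")
    strains: set[str] = set()
    for cell in df["strains"]:
        strains.update(s.strip() for s in str(cell).split("+"))
    return StrainPanel(tuple(sorted(strains)))


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis the inputs support; write a report bundle to config.out.

    Function and tree inputs are optional: the corresponding sections are
    skipped with a logged notice. Any failure leaves a FAILED marker naming
    the error next to whatever partial outputs were already written.
    """
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        report = _run(config)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return report


def _run(config: RunConfig) -> dict:
    out = config.out
    panel = config.panel or infer_panel(config.layout)
    layout = read_plate_layout(config.layout, panel)
    series = read_od_timeseries(config.od, layout)

    growth_cfg = GrowthConfig(theta=config.theta)
    features = extract_all(series, growth_cfg)
    table = build_fitness_table(features, layout)
    table.to_tsv(out / "fitness.tsv")

    calls = classify_panel(table, alpha=config.alpha, exclude_monocultures=config.exclude_monocultures)
    overall = aggregate_calls(calls)
    write_tsv(calls_to_frame(calls), out / "social_calls.tsv")
    write_tsv(overall_to_frame(overall), out / "social_overall.tsv")

    richness_frames, cumulative_frames, gt1_frames = [], [], []
    for condition in table.conditions:
        for metric in ("n", "k"):
            richness_frames.append(richness_fitness(table, metric, condition).to_frame())
            cume = cumulative_best(table, metric, condition)
            cumulative_frames.append(cume.to_frame())
            gt1_frames.append(cume.gt1)
    write_tsv(pd.concat(richness_frames, ignore_index=True), out / "richness.tsv")
    write_tsv(pd.concat(cumulative_frames, ignore_index=True), out / "cumulative.tsv")
    write_tsv(pd.concat(gt1_frames, ignore_index=True), out / "cumulative_gt1.tsv")

    function = read_function_table(config.function) if config.function else None
    stability = cv_stability(table, function)
    write_tsv(stability.per_consortium, out / "stability.tsv")
    write_tsv(stability.per_richness, out / "stability_median.tsv")
    write_tsv(stability.regressions, out / "stability_regressions.tsv")
    if stability.function_regressions is not None:
        write_tsv(stability.function_regressions, out / "function_richness_regressions.tsv")

    top_frames = []
    for condition in table.conditions:
        ranked = rank_consortia(table, condition, top=config.top)
        ranked.insert(0, "condition", condition)
        top_frames.append(ranked)
    top = pd.concat(top_frames, ignore_index=True)
    write_tsv(top, out / "top_consortia.tsv")

    report: dict = {
        "version": __version__,
        "config": config.echo(),
        "n_strains": len(panel),
        "n_consortia": len(layout.consortia),
        "n_wells": len(layout.wells),
        "conditions": table.conditions,
        "social_overall": overall,
        "top_consortia": {
            c: top[top["condition"] == c]["consortium"].tolist() for c in table.conditions
        },
    }

    if function is not None:
        comparison = compare_function_groups(
            function, overall, table.membership, test=config.group_test
        )
        correlations = pd.concat(
            [correlate_fitness_function(table, function, c) for c in table.conditions],
            ignore_index=True,
        )
        write_tsv(correlations, out / "fitness_function_correlations.tsv")
        write_json(comparison.to_dict(), out / "function_group_comparison.json")
        report["function_group_comparison"] = comparison.to_dict()
        report["fitness_function_correlations"] = correlations.to_dict(orient="records")
    else:
        logger.info("no function table supplied; skipping function analyses")

    if config.tree is not None:
        tree = StrainTree.from_newick(config.tree)
        consortia = sorted(layout.consortia.values(), key=lambda c: c.canonical_id)
        dm = unifrac_matrix(tree, consortia)
        dm_frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        dm_frame.round(6).to_csv(out / "unifrac.tsv", sep="\t", float_format="%.6g")
        phylo_condition = config.phylo_condition or table.conditions[0]
        covariate = table.consortium_means(config.phylo_metric, phylo_condition)
        ad = adonis(dm, covariate, n_perm=config.n_perm, seed=config.seed)
        patristic = patristic_fitness_regression(tree, consortia, covariate)
        phylo_report = {
            "condition": phylo_condition,
            "metric": config.phylo_metric,
            "adonis": {
                "pseudo_f": ad.pseudo_f,
                "r2": ad.r2,
                "p": ad.p,
                "n_perm": ad.n_perm,
                "seed": ad.seed,
            },
            "max_patristic_regression": {k: float(v) for k, v in patristic.items()},
        }
        write_json(phylo_report, out / "adonis.json")
        report["phylo"] = phylo_report
    else:
        logger.info("no tree supplied; skipping UniFrac/adonis analyses")

    write_json(config.echo(), out / "config.json")
    write_json(report, out / "report.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "layout": config.layout.name,
            "od": config.od.name,
            "function": config.function.name if config.function else None,
            "tree": config.tree.name if config.tree else None,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    write_json(manifest, out / "manifest.json")
    return report
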
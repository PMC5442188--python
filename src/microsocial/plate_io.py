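"""Plate layouts, OD time series, and the full combinatorial consortium design.

A full combinatorial growth experiment assays every non-empty subset
(*consortium*) of a strain panel: 2**N - 1 consortia for N strains, e.g. 127
consortia for a seven-strain panel, each grown in replicate wells of a
96-well plate with optical density (OD, 595 nm) read at regular intervals.

This module owns the bookkeeping: the strain panel, consortium identity,
the well -> (consortium, condition, replicate) layout, and readers for the
two plate-reader CSV dialects (wide: ``time_h`` plus one column per well;
long: ``well,time_h,od``).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: separator for strain lists in layout files ("-" may occur inside strain IDs)
STRAIN_SEP = "+"

LAYOUT_COLUMNS = ("well", "strains", "condition", "replicate")


class LayoutError(ValueError):
    """Malformed or internally inconsistent plate layout / OD table."""


@dataclass(frozen=True)
class StrainPanel:
    """Ordered collection of unique strain identifiers.

    The panel fixes the universe of strains; consortia are validated against
    it and enumeration order is derived from it.
    """

    strains: tuple[str, ...]

    def __post_init__(self) -> None:
        strains = tuple(str(s) for s in self.strains)
        object.__setattr__(self, "strains", strains)
        if not strains:
            raise ValueError("strain panel must not be empty")
        if len(set(strains)) != len(strains):
            dupes = sorted({s for s in strains if strains.count(s) > 1})
            raise ValueError(f"duplicate strain IDs in panel: {dupes}")
        for s in strains:
            if not s or STRAIN_SEP in s or "," in s:
                raise ValueError(f"invalid strain ID {s!r}")

    def __len__(self) -> int:
        return len(self.strains)

    def __iter__(self) -> Iterator[str]:
        return iter(self.strains)

    def __contains__(self, strain: object) -> bool:
        return strain in self.strains


def canonical_id(members: Iterable[str]) -> str:
    """Canonical consortium ID: members sorted, joined with "-".

    Falls back to "+" when any member itself contains a dash, so the ID
    remains unambiguously parseable.
    """
    members = sorted(members)
    sep = "+" if any("-" in m for m in members) else "-"
    return sep.join(members)


@dataclass(frozen=True, order=True)
class Consortium:
    """A non-empty set of strains co-cultured in one well."""

    members: frozenset[str] = field(compare=False)
    sort_index: tuple[int, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        members = frozenset(str(m) for m in self.members)
        if not members:
            raise ValueError("consortium must have at least one member")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "sort_index", (len(members), canonical_id(members)))

    @property
    def richness(self) -> int:
        return len(self.members)

    @property
    def canonical_id(self) -> str:
        return self.sort_index[1]

    def __contains__(self, strain: object) -> bool:
        return strain in self.members

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_id


def enumerate_consortia(panel: StrainPanel | Sequence[str], min_size: int = 1) -> list[Consortium]:
    """All subsets of the panel with at least ``min_size`` members.

    Deterministic order: by richness, then lexicographic canonical ID.
    For a panel of N strains and ``min_size=1`` this yields 2**N - 1
    consortia (127 for the canonical seven-strain design).
    """
    if not isinstance(panel, StrainPanel):
        panel = StrainPanel(tuple(panel))
    n = len(panel)
    if not 1 <= min_size <= n:
        raise ValueError(f"min_size must be in [1, {n}], got {min_size}")
    out: list[Consortium] = []
    for r in range(min_size, n + 1):
        level = [Consortium(frozenset(c)) for c in itertools.combinations(panel.strains, r)]
        level.sort(key=lambda c: c.canonical_id)
        out.extend(level)
    return out


@dataclass
class PlateLayout:
    """Validated mapping of wells to (consortium, condition, replicate)."""

    panel: StrainPanel
    rows: pd.DataFrame  # columns: well, consortium, condition, replicate
    consortia: dict[str, Consortium]  # canonical ID -> Consortium

    @property
    def wells(self) -> list[str]:
        return list(self.rows["well"])

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.rows["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def membership(self) -> dict[str, frozenset[str]]:
        return {cid: c.members for cid, c in self.consortia.items()}


def build_layout(
    records: Iterable[tuple[str, Iterable[str], str, int]],
    panel: StrainPanel,
) -> PlateLayout:
    """Assemble and validate a layout from (well, members, condition, replicate) records."""
    rows = []
    consortia: dict[str, Consortium] = {}
    seen_triples: set[tuple[str, str, int]] = set()
    seen_wells: set[str] = set()
    for i, (well, members, condition, replicate) in enumerate(records):
        well = str(well)
        members = [str(m).strip() for m in members]
        unknown = [m for m in members if m not in panel]
        if unknown:
            raise LayoutError(
                f"row {i} (well {well!r}): strain(s) {unknown} not in panel {list(panel.strains)}"
            )
        consortium = Consortium(frozenset(members))
        cid = consortium.canonical_id
        consortia.setdefault(cid, consortium)
        replicate = int(replicate)
        triple = (cid, str(condition), replicate)
        if triple in seen_triples:
            raise LayoutError(f"row {i} (well {well!r}): duplicate (consortium, condition, replicate) {triple}")
        seen_triples.add(triple)
        if well in seen_wells:
            raise LayoutError(f"row {i}: duplicate well ID {well!r}")
        seen_wells.add(well)
        rows.append((well, cid, str(condition), replicate))
    if not rows:
        raise LayoutError("layout has no rows")
    frame = pd.DataFrame(rows, columns=["well", "consortium", "condition", "replicate"])
    return PlateLayout(panel=panel, rows=frame, consortia=consortia)


def read_plate_layout(path: str | Path, panel: StrainPanel) -> PlateLayout:
    """Read a layout CSV with columns ``well,strains,condition,replicate``.

    The ``strains`` field is a "+"-separated member list (e.g. ``MS2+SH7``).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: layout is missing required column(s) {missing}")
    records = (
        (row.well, str(row.strains).split(STRAIN_SEP), row.condition, row.replicate)
        for row in df.itertuples(index=False)
    )
    return build_layout(records, panel)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write a layout back to the CSV dialect accepted by :func:`read_plate_layout`."""
    out = layout.rows.copy()
    out["strains"] = [
        STRAIN_SEP.join(sorted(layout.consortia[cid].members)) for cid in out["consortium"]
    ]
    out[list(LAYOUT_COLUMNS)].to_csv(path, index=False)


@dataclass
class ODTimeSeries:
    """Optical-density readings for one well at strictly increasing times (hours)."""

    well: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise LayoutError(f"well {self.well!r}: times and od must be 1-D and equal length")
        if self.times.size < 4:
            raise LayoutError(f"well {self.well!r}: need at least 4 time points, got {self.times.size}")
        if not np.all(np.diff(self.times) > 0):
            raise LayoutError(f"well {self.well!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise LayoutError(f"well {self.well!r}: OD values must be finite")

    def __len__(self) -> int:
        return self.times.size


def _series_from_wide(df: pd.DataFrame, layout: PlateLayout, source: str) -> dict[str, ODTimeSeries]:
    times = pd.to_numeric(df["time_h"], errors="raise").to_numpy(dtype=float)
    available = [c for c in df.columns if c != "time_h"]
    out: dict[str, ODTimeSeries] = {}
    for well in layout.wells:
        if well not in available:
            raise LayoutError(f"{source}: layout well {well!r} absent from OD table")
        try:
            od = pd.to_numeric(df[well], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise LayoutError(f"{source}: non-numeric OD in column {well!r}: {exc}") from exc
        out[well] = ODTimeSeries(well, times, od)
    extra = [c for c in available if c not in out]
    if extra:
        logger.warning("%s: ignoring %d column(s) not in layout: %s", source, len(extra), extra)
    return out


def _series_from_long(df: pd.DataFrame, layout: PlateLayout, source: str) -> dict[str, ODTimeSeries]:
    out: dict[str, ODTimeSeries] = {}
    grouped = dict(tuple(df.groupby("well", sort=False)))
    for well in layout.wells:
        if well not in grouped:
            raise LayoutError(f"{source}: layout well {well!r} absent from OD table")
        g = grouped[well]
        try:
            times = pd.to_numeric(g["time_h"], errors="raise").to_numpy(dtype=float)
            od = pd.to_numeric(g["od"], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise LayoutError(f"{source}: non-numeric value for well {well!r}: {exc}") from exc
        out[well] = ODTimeSeries(well, times, od)
    extra = sorted(set(grouped) - set(out))
    if extra:
        logger.warning("%s: ignoring %d well(s) not in layout: %s", source, len(extra), extra)
    return out


def read_od_timeseries(path: str | Path, layout: PlateLayout) -> dict[str, ODTimeSeries]:
    """Read an OD table (wide or long dialect, auto-detected) keyed by well.

    Wells present in the file but absent from the layout are ignored with a
    logged warning; a layout well missing from the file is an error.
    """
    df = pd.read_csv(path)
    source = str(path)
    if {"well", "time_h", "od"}.issubset(df.columns):
        return _series_from_long(df, layout, source)
    if len(df.columns) >= 2 and df.columns[0] == "time_h":
        return _series_from_wide(df, layout, source)
    raise LayoutError(
        f"{source}: unrecognized OD table header {list(df.columns)[:6]}; expected wide "
        "(time_h + well columns) or long (well,time_h,od) format"
    )


def write_od_timeseries(series: Mapping[str, ODTimeSeries], path: str | Path) -> None:
    """Write series to the wide CSV dialect (shared time grid required)."""
    wells = list(series)
    if not wells:
        raise LayoutError("no series to write")
    times = series[wells[0]].times
    for w in wells[1:]:
        if not np.array_equal(series[w].times, times):
            raise LayoutError("wide OD output requires a shared time grid across wells")
    df = pd.DataFrame({"time_h": times, **{w: series[w].od for w in wells}})
    df.to_csv(path, index=False, float_format="%.6g")
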
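"""Data model and I/O for tracked single-cell lineages.

A lineage experiment yields, per tracked cell, a time series of mean
nuclear fluorescence intensity (arbitrary fluorescence units, a.f.u.)
sampled on a fixed interval (default 5 min), plus a parent link.  This
module builds a validated :class:`LineageForest` from such track tables,
computes per-cell summaries (lifetime-mean level, cell-cycle duration,
pulse frequency) and answers kinship queries (sister / cousin / second
cousin, division distance).

Conventions
-----------
* Internal time unit is minutes; in differentiation runs t = 0 is the
  moment the stimulus is added.
* A cell's lifetime is the half-open interval [birth, division).  The
  division timestamp is the first frame at which the two daughters are
  quantified separately; the mother's trace ends one frame earlier.
* Founders first seen mid-life carry ``birth_time = None``; they anchor
  lineage relations but are excluded from cycle-duration and
  lifetime-mean feature sets.
* Division is strictly binary: a parent with one child or more than two
  children is a tracking artifact and raises a validation error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_SAMPLING_INTERVAL = 5.0  # minutes

__all__ = [
    "CellRecord",
    "CellSummary",
    "LineageForest",
    "LineageError",
    "StructuralError",
    "ValidationError",
    "read_track_table",
    "write_track_table",
    "cycle_duration",
    "mean_level",
    "kinship",
    "filter_complete_before",
    "summarize_cells",
]


class LineageError(Exception):
    """Base class for lineage construction problems."""


class StructuralError(LineageError):
    """Unresolvable parent link or cyclic parentage."""


class ValidationError(LineageError):
    """Malformed trace or non-binary division."""


@dataclass
class CellRecord:
    """One tracked cell: identity, parentage, and its intensity trace.

    ``times`` are minutes since experiment start; ``levels`` are mean
    nuclear intensities in a.f.u.; ``frames`` are the imaging frame
    indices.  All three arrays share one strictly time-ordered grid.
    """

    cell_id: str
    parent_id: str | None
    frames: np.ndarray
    times: np.ndarray
    levels: np.ndarray
    birth_time: float | None = None
    division_time: float | None = None
    children: tuple[str, str] | None = None
    pulse_eligible: bool = True  # False if trace had gaps too wide to interpolate

    @property
    def complete(self) -> bool:
        """True iff both the cell's birth and its own division were observed."""
        return self.birth_time is not None and self.division_time is not None

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)


@dataclass
class CellSummary:
    cell_id: str
    mean_level: float
    cycle_duration: float | None  # hours
    pulse_frequency: float | None = None  # pulses per hour


@dataclass
class LineageForest:
    """Parent-linked forest of :class:`CellRecord` keyed by cell id."""

    cells: dict[str, CellRecord]
    roots: list[str] = field(default_factory=list)
    endpoints: pd.DataFrame | None = None  # side table of endpoint columns
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.cells

    def __len__(self) -> int:
        return len(self.cells)

    def __getitem__(self, cell_id: str) -> CellRecord:
        return self.cells[cell_id]

    def children_of(self, cell_id: str) -> tuple[str, ...]:
        ch = self.cells[cell_id].children
        return ch if ch is not None else ()

    def parent_of(self, cell_id: str) -> str | None:
        return self.cells[cell_id].parent_id

    def leaves(self) -> list[str]:
        return [cid for cid, c in self.cells.items() if c.children is None]

    def root_of(self, cell_id: str) -> str:
        cid = cell_id
        seen = set()
        while self.cells[cid].parent_id is not None:
            if cid in seen:  # pragma: no cover - guarded at construction
                raise StructuralError(f"cycle through {cid}")
            seen.add(cid)
            cid = self.cells[cid].parent_id
        return cid

    def ancestors(self, cell_id: str) -> list[str]:
        """Ancestor ids from parent upward to the root."""
        out = []
        cid = self.cells[cell_id].parent_id
        while cid is not None:
            out.append(cid)
            cid = self.cells[cid].parent_id
        return out

    def descendants(self, cell_id: str) -> list[str]:
        out: list[str] = []
        stack = list(self.children_of(cell_id))
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(self.children_of(cid))
        return out

    def to_json(self) -> str:
        """Nested-children JSON export of the forest topology and traces."""

        def node(cid: str) -> dict:
            c = self.cells[cid]
            return {
                "cell_id": c.cell_id,
                "birth_time": c.birth_time,
                "division_time": c.division_time,
                "frames": c.frames.tolist(),
                "times": c.times.tolist(),
                "levels": c.levels.tolist(),
                "children": [node(k) for k in self.children_of(cid)],
            }

        return json.dumps({"roots": [node(r) for r in self.roots]}, indent=1)


def _interpolate_gaps(
    frames: np.ndarray,
    times: np.ndarray,
    levels: np.ndarray,
    interval: float,
    gap_tolerance: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Fill dropped frames by linear interpolation onto the regular grid.

    Returns the filled arrays plus a flag that is False when any gap
    exceeded ``gap_tolerance`` missing frames (such cells keep their
    interpolated trace but are disqualified from pulse analysis).
    """
    full = np.arange(frames[0], frames[-1] + 1)
    if len(full) == len(frames):
        return frames, times, levels, True
    gaps = np.diff(frames) - 1
    ok = bool(gaps.max() <= gap_tolerance)
    t0 = times[0]
    full_times = t0 + (full - frames[0]) * interval
    full_levels = np.interp(full_times, times, levels)
    return full, full_times, full_levels, ok


def read_track_table(
    path,
    *,
    sep: str = ",",
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    gap_tolerance: int = 1,
) -> LineageForest:
    """Read a delimited track table into a validated :class:`LineageForest`.

    Expected columns: ``cell_id, parent_id, frame, time_min, level_afu``
    with optional endpoint columns ``cdx2_afu`` and ``dapi_afu`` (kept as
    a side table, one row per cell from its last frame).  An empty
    ``parent_id`` marks a founder.

    Raises
    ------
    StructuralError
        If a parent_id does not resolve to a cell in the table.
    ValidationError
        If frames are non-monotone within a cell or a parent has one or
        more than two children.
    """
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "parent_id": str})
    required = {"cell_id", "parent_id", "frame", "time_min", "level_afu"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"track table missing columns: {sorted(missing)}")
    df["parent_id"] = df["parent_id"].fillna("")
    return build_forest(df, sampling_interval=sampling_interval, gap_tolerance=gap_tolerance)


def build_forest(
    df: pd.DataFrame,
    *,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    gap_tolerance: int = 1,
) -> LineageForest:
    """Construct a forest from a long-format track DataFrame.

    Construction is order-independent: rows are sorted by (cell, frame)
    before assembly.
    """
    df = df.sort_values(["cell_id", "frame"], kind="mergesort")
    cells: dict[str, CellRecord] = {}
    child_map: dict[str, list[str]] = {}
    endpoint_rows = []

    for cid, grp in df.groupby("cell_id", sort=False):
        frames = grp["frame"].to_numpy(dtype=int)
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise ValidationError(f"cell {cid}: frames not strictly increasing")
        times = grp["time_min"].to_numpy(dtype=float)
        levels = grp["level_afu"].to_numpy(dtype=float)
        frames, times, levels, pulse_ok = _interpolate_gaps(
            frames, times, levels, sampling_interval, gap_tolerance
        )
        parent = grp["parent_id"].iloc[0]
        parent = None if parent in ("", None) else str(parent)
        cells[str(cid)] = CellRecord(
            cell_id=str(cid),
            parent_id=parent,
            frames=frames,
            times=times,
            levels=levels,
            pulse_eligible=pulse_ok,
        )
        if parent is not None:
            child_map.setdefault(parent, []).append(str(cid))
        for col in ("cdx2_afu", "dapi_afu", "oct4_end_afu"):
            if col in grp.columns and grp[col].notna().any():
                endpoint_rows.append(
                    {"cell_id": str(cid), col: float(grp[col].dropna().iloc[-1])}
                )

    for parent, kids in child_map.items():
        if parent not in cells:
            raise StructuralError(f"parent {parent!r} of {kids} not in table")
        if len(kids) != 2:
            raise ValidationError(
                f"cell {parent} has {len(kids)} children; divisions must be binary"
            )

    # cycle check (defensive; a well-formed table cannot encode one)
    for cid in cells:
        seen = set()
        cur: str | None = cid
        while cur is not None:
            if cur in seen:
                raise StructuralError(f"parent links form a cycle through {cur}")
            seen.add(cur)
            cur = cells[cur].parent_id if cur in cells else None

    # birth/division anchors: birth = first own frame when the parent is
    # observed; division = first frame of the daughters.
    for parent, kids in child_map.items():
        kids_sorted = sorted(kids)
        div_t = min(cells[k].times[0] for k in kids_sorted)
        cells[parent].children = (kids_sorted[0], kids_sorted[1])
        cells[parent].division_time = float(div_t)
    for cid, rec in cells.items():
        if rec.parent_id is not None:
            rec.birth_time = float(rec.times[0])

    roots = sorted(cid for cid, c in cells.items() if c.parent_id is None)
    endpoints = None
    if endpoint_rows:
        endpoints = (
            pd.DataFrame(endpoint_rows).groupby("cell_id", as_index=False).first()
        )
    return LineageForest(
        cells=cells, roots=roots, endpoints=endpoints, sampling_interval=sampling_interval
    )


def write_track_table(forest: LineageForest, path, *, sep: str = ",") -> None:
    """Write a forest back to the delimited track-table format."""
    rows = []
    ep = None
    if forest.endpoints is not None:
        ep = forest.endpoints.set_index("cell_id")
    for cid in sorted(forest.cells):
        c = forest.cells[cid]
        for i in range(c.n_samples):
            row = {
                "cell_id": c.cell_id,
                "parent_id": c.parent_id if c.parent_id is not None else "",
                "frame": int(c.frames[i]),
                "time_min": c.times[i],
                "level_afu": c.levels[i],
            }
            if ep is not None and i == c.n_samples - 1 and cid in ep.index:
                for col in ep.columns:
                    v = ep.loc[cid, col]
                    if pd.notna(v):
                        row[col] = v
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def cycle_duration(cell: CellRecord) -> float | None:
    """Cell-cycle duration in hours, or None when birth or division is censored."""
    if not cell.complete:
        return None
    return (cell.division_time - cell.birth_time) / 60.0


def mean_level(cell: CellRecord) -> float:
    """Lifetime-average level (a.f.u.): arithmetic mean of the trace."""
    if cell.n_samples == 0:
        raise ValidationError(f"cell {cell.cell_id}: empty trace")
    return float(np.mean(cell.levels))


def summarize_cells(
    forest: LineageForest, pulse_counts: Mapping[str, int] | None = None
) -> dict[str, CellSummary]:
    """Per-cell summaries; pulse frequency filled when counts are supplied."""
    out = {}
    for cid, cell in forest.cells.items():
        dur = cycle_duration(cell)
        pf = None
        if pulse_counts is not None and dur is not None and cid in pulse_counts:
            pf = pulse_counts[cid] / dur
        out[cid] = CellSummary(cid, mean_level(cell), dur, pf)
    return out


def _depth(forest: LineageForest, cid: str) -> int:
    d = 0
    while forest.cells[cid].parent_id is not None:
        cid = forest.cells[cid].parent_id
        d += 1
    return d


def kinship(forest: LineageForest, id1: str, id2: str) -> tuple[str, int | None]:
    """Classify the relationship between two cells.

    Returns ``(category, division_distance)`` where category is one of
    ``sister`` (same parent), ``cousin`` (parents are sisters),
    ``second_cousin`` (grandparents are sisters) or ``other``, and
    division_distance counts the division events on the tree path
    between the two cells (None for cells in different trees).
    """
    for cid in (id1, id2):
        if cid not in forest:
            raise KeyError(f"unknown cell id {cid!r}")
    if id1 == id2:
        return "other", 0

    anc1 = [id1] + forest.ancestors(id1)
    anc2 = [id2] + forest.ancestors(id2)
    if anc1[-1] != anc2[-1]:
        return "other", None
    set2 = {c: i for i, c in enumerate(anc2)}
    for i, c in enumerate(anc1):
        if c in set2:
            dist = i + set2[c]
            break

    def nth_parent(cid: str, n: int) -> str | None:
        for _ in range(n):
            cid = forest.cells[cid].parent_id
            if cid is None:
                return None
        return cid

    p1, p2 = nth_parent(id1, 1), nth_parent(id2, 1)
    if p1 is not None and p1 == p2:
        return "sister", dist
    g1, g2 = nth_parent(id1, 2), nth_parent(id2, 2)
    if None not in (p1, p2) and p1 != p2 and g1 is not None and g1 == g2:
        return "cousin", dist
    gg1, gg2 = nth_parent(id1, 3), nth_parent(id2, 3)
    if None not in (g1, g2) and g1 != g2 and gg1 is not None and gg1 == gg2:
        return "second_cousin", dist
    return "other", dist


def filter_complete_before(forest: LineageForest, t0: float) -> set[str]:
    """Ids of cells whose full cycle (birth and division) ended by ``t0`` minutes."""
    return {
        cid
        for cid, c in forest.cells.items()
        if c.complete and c.division_time <= t0
    }


def sister_pairs(forest: LineageForest) -> list[tuple[str, str]]:
    """All (sorted) sister pairs in the forest."""
    return [
        forest.cells[cid].children
        for cid in forest.cells
        if forest.cells[cid].children is not None
    ]
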
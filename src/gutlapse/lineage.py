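"""Lineage-tree reconstruction from per-cell track tables.

Tracks carry one observation per frame (position in µm, nuclear area,
GFP). Trees are assembled either directly from annotated parent ids or,
when those are absent, by linking a track that ends at frame ``f`` to the
two tracks appearing at ``f + 1`` whose start positions are nearest to the
mother's last position (both within ``link_radius_um``). A division always
has exactly two daughters whose first frame is the mother's last frame
plus one — the mitotic frame itself is unscorable because the nuclear GFP
signal disperses at nuclear-envelope breakdown.

Cell-cycle duration is the frame span from a cell's appearance (by
division) to its own division, times the frame interval.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POINT_COLUMNS = ["frame", "x_um", "y_um", "z_um", "area_um2", "gfp"]


class LineageError(ValueError):
    pass


class UnresolvedDivisionError(LineageError):
    """More than two candidate daughters within the linking radius."""


@dataclasses.dataclass
class Track:
    """One cell's ordered per-frame observations with an optional parent."""

    cell_id: int
    parent_id: int | None
    points: pd.DataFrame  # POINT_COLUMNS (+ 'interpolated' when gap-filled)

    def __post_init__(self) -> None:
        frames = self.points["frame"].to_numpy()
        if len(frames) == 0:
            raise LineageError(f"track {self.cell_id} has no points")
        if np.any(np.diff(frames) <= 0):
            raise LineageError(f"track {self.cell_id}: frames must strictly increase")
        if np.any(np.diff(frames) != 1):
            raise LineageError(f"track {self.cell_id}: frames must be contiguous")

    @property
    def first_frame(self) -> int:
        return int(self.points["frame"].iloc[0])

    @property
    def last_frame(self) -> int:
        return int(self.points["frame"].iloc[-1])

    def at(self, frame: int) -> pd.Series | None:
        sel = self.points[self.points["frame"] == frame]
        return None if sel.empty else sel.iloc[0]

    def position(self, frame: int) -> np.ndarray | None:
        row = self.at(frame)
        if row is None:
            return None
        return np.array([row["x_um"], row["y_um"], row["z_um"]])


@dataclasses.dataclass(frozen=True)
class DivisionEvent:
    mother_id: int
    daughter_ids: tuple[int, int]
    frame: int  # mother's last observed frame
    flat_flag: bool | None = None


@dataclasses.dataclass
class TreeNode:
    cell_id: int
    parent_id: int | None
    first_frame: int
    last_frame: int


@dataclasses.dataclass
class LineageTree:
    """Rooted tree of tracks with its division events."""

    root: int
    nodes: dict[int, TreeNode]
    children: dict[int, tuple[int, ...]]
    divisions: list[DivisionEvent]
    tracks: dict[int, Track] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        for div in self.divisions:
            if len(div.daughter_ids) != 2:
                raise LineageError("a division must have exactly two daughters")
            for d in div.daughter_ids:
                if self.nodes[d].first_frame != div.frame + 1:
                    raise LineageError(
                        f"daughter {d} must appear the frame after mother "
                        f"{div.mother_id} disappears"
                    )
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise LineageError("lineage tree contains a cycle")
            seen.add(nid)
            stack.extend(self.children.get(nid, ()))
        if seen != set(self.nodes):
            raise LineageError("tree nodes unreachable from root")

    def dividing_cells(self) -> set[int]:
        return {d.mother_id for d in self.divisions}

    def division_frame_of(self, cell_id: int) -> int | None:
        for d in self.divisions:
            if d.mother_id == cell_id:
                return d.frame
        return None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "root": self.root,
            "nodes": [
                {"id": n.cell_id, "parent": n.parent_id,
                 "first_frame": n.first_frame, "last_frame": n.last_frame}
                for n in sorted(self.nodes.values(), key=lambda n: n.cell_id)
            ],
            "divisions": [
                {"mother": d.mother_id, "daughters": list(d.daughter_ids),
                 "frame": d.frame, "flat_flag": d.flat_flag}
                for d in sorted(self.divisions, key=lambda d: (d.frame, d.mother_id))
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LineageTree":
        p = Path(str(source))
        data = json.loads(p.read_text() if p.exists() else str(source))
        nodes = {
            n["id"]: TreeNode(n["id"], n["parent"], n["first_frame"], n["last_frame"])
            for n in data["nodes"]
        }
        children: dict[int, list[int]] = {}
        for n in nodes.values():
            if n.parent_id is not None:
                children.setdefault(n.parent_id, []).append(n.cell_id)
        divisions = [
            DivisionEvent(d["mother"], tuple(d["daughters"]), d["frame"],
                          d.get("flat_flag"))
            for d in data["divisions"]
        ]
        return cls(
            root=data["root"], nodes=nodes,
            children={k: tuple(sorted(v)) for k, v in children.items()},
            divisions=divisions,
        )


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Split a long-format track table into validated Track objects.

    Gap policy: a single missing frame is filled by linear interpolation
    and flagged; a gap of two or more frames splits the track, the distal
    part becoming a parentless fragment whose id is ``1000000 * k +
    cell_id`` (fragment index k >= 1).
    """
    required = {"cell_id", "frame", "x_um", "y_um", "z_um"}
    missing = required - set(table.columns)
    if missing:
        raise LineageError(f"track table missing columns {sorted(missing)}")
    df = table.copy()
    for col in ("area_um2", "gfp"):
        if col not in df.columns:
            df[col] = np.nan
    has_parent = "parent_id" in df.columns
    tracks: list[Track] = []
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        if grp["frame"].duplicated().any():
            raise LineageError(f"track {cid}: duplicate frames")
        parent = None
        if has_parent:
            pv = grp["parent_id"].iloc[0]
            parent = None if pd.isna(pv) else int(pv)
        segments = _split_on_gaps(grp)
        for k, seg in enumerate(segments):
            seg_id = int(cid) if k == 0 else 1000000 * k + int(cid)
            seg_parent = parent if k == 0 else None
            if k > 0:
                warnings.warn(
                    f"track {cid} split at a >=2-frame gap; fragment {seg_id} "
                    "treated as a new root",
                    stacklevel=2,
                )
            pts = seg[POINT_COLUMNS + (["interpolated"] if "interpolated" in seg else [])]
            tracks.append(Track(seg_id, seg_parent, pts.reset_index(drop=True)))
    return tracks


def _split_on_gaps(grp: pd.DataFrame) -> list[pd.DataFrame]:
    frames = grp["frame"].to_numpy()
    gaps = np.diff(frames)
    cut_points = np.nonzero(gaps >= 3)[0]  # gap of >= 2 missing frames
    segments = []
    start = 0
    for cut in list(cut_points) + [len(frames) - 1]:
        seg = grp.iloc[start:cut + 1].copy()
        seg["interpolated"] = False
        seg = _fill_single_gaps(seg)
        segments.append(seg)
        start = cut + 1
    return segments


def _fill_single_gaps(seg: pd.DataFrame) -> pd.DataFrame:
    frames = seg["frame"].to_numpy()
    inserts = []
    for i, gap in enumerate(np.diff(frames)):
        if gap == 2:  # one missing frame: interpolate, flag
            lo, hi = seg.iloc[i], seg.iloc[i + 1]
            row = {"frame": int(frames[i]) + 1, "interpolated": True}
            for col in ("x_um", "y_um", "z_um", "area_um2", "gfp"):
                row[col] = (lo[col] + hi[col]) / 2.0
            for col in seg.columns:
                if col not in row:
                    row[col] = lo[col]
            inserts.append(row)
    if inserts:
        seg = pd.concat([seg, pd.DataFrame(inserts)], ignore_index=True)
        seg = seg.sort_values("frame").reset_index(drop=True)
    return seg


def _trees_from_links(tracks: dict[int, Track],
                      parent_of: dict[int, int | None]) -> list[LineageTree]:
    children: dict[int, list[int]] = {}
    roots = []
    for cid, parent in parent_of.items():
        if parent is None:
            roots.append(cid)
        else:
            children.setdefault(parent, []).append(cid)
    trees = []
    for root in sorted(roots):
        member_ids = []
        stack = [root]
        while stack:
            nid = stack.pop()
            member_ids.append(nid)
            stack.extend(children.get(nid, ()))
        nodes = {
            cid: TreeNode(cid, parent_of[cid], tracks[cid].first_frame,
                          tracks[cid].last_frame)
            for cid in member_ids
        }
        divisions = []
        for cid in member_ids:
            kids = tuple(sorted(children.get(cid, ())))
            if len(kids) == 2:
                divisions.append(DivisionEvent(cid, kids, nodes[cid].last_frame))
            elif len(kids) == 1:
                raise LineageError(
                    f"cell {cid} has a single daughter; divisions need two"
                )
            elif len(kids) > 2:
                raise UnresolvedDivisionError(
                    f"cell {cid} linked to {len(kids)} daughters {kids}"
                )
        tree = LineageTree(
            root=root, nodes=nodes,
            children={k: tuple(sorted(v)) for k, v in children.items()
                      if k in nodes},
            divisions=sorted(divisions, key=lambda d: (d.frame, d.mother_id)),
            tracks={cid: tracks[cid] for cid in member_ids},
        )
        tree.validate()
        trees.append(tree)
    return trees


def build_lineage_trees(
    track_table: pd.DataFrame | Sequence[Track],
    link_radius_um: float = 10.0,
) -> list[LineageTree]:
    """Assemble lineage trees from a track table or pre-built tracks.

    With annotated parent ids the trees are assembled directly. Without
    them, a mother whose track ends at frame ``f`` is linked to the
    tracks appearing at ``f + 1`` whose start positions lie within
    ``link_radius_um`` of the mother's last 3D position: exactly two
    candidates make a division, more raise
    :class:`UnresolvedDivisionError`, and an appearing track with no
    candidate mother becomes a new root (with a warning).
    """
    if isinstance(track_table, pd.DataFrame):
        tracks = tracks_from_table(track_table)
    else:
        tracks = list(track_table)
    by_id = {t.cell_id: t for t in tracks}
    if any(t.parent_id is not None for t in tracks):
        parent_of: dict[int, int | None] = {}
        for t in tracks:
            if t.parent_id is not None and t.parent_id not in by_id:
                raise LineageError(
                    f"track {t.cell_id} references unknown parent {t.parent_id}"
                )
            parent_of[t.cell_id] = t.parent_id
        return _trees_from_links(by_id, parent_of)
    return _link_parentless(by_id, link_radius_um)


def _link_parentless(by_id: dict[int, Track],
                     link_radius_um: float) -> list[LineageTree]:
    parent_of: dict[int, int | None] = {cid: None for cid in by_id}
    ends: dict[int, list[int]] = {}
    starts: dict[int, list[int]] = {}
    for cid, tr in by_id.items():
        ends.setdefault(tr.last_frame, []).append(cid)
        starts.setdefault(tr.first_frame, []).append(cid)
    for f in sorted(ends):
        newborn = sorted(starts.get(f + 1, ()))
        if not newborn:
            continue
        mothers = sorted(ends[f])
        mother_pos = {m: by_id[m].position(f) for m in mothers}
        dist = np.full((len(newborn), len(mothers)), np.inf)
        for i, c in enumerate(newborn):
            cpos = by_id[c].position(f + 1)
            for j, m in enumerate(mothers):
                d = float(np.linalg.norm(cpos - mother_pos[m]))
                if d <= link_radius_um:
                    dist[i, j] = d
        # a newborn whose only feasible mother already has two other such
        # exclusive candidates is genuinely ambiguous
        for j, m in enumerate(mothers):
            exclusive = [
                newborn[i] for i in range(len(newborn))
                if np.isfinite(dist[i, j]) and np.isfinite(dist[i]).sum() == 1
            ]
            if len(exclusive) > 2:
                raise UnresolvedDivisionError(
                    f"mother {m} ending at frame {f} has {len(exclusive)} "
                    f"candidate daughters within {link_radius_um} µm: "
                    f"{exclusive}"
                )
        # competition between simultaneous divisions: greedy matching of
        # mothers to newborn pairs by the distance between the mother's
        # last position and the pair midpoint — cytokinesis splits the
        # mother in place, so true daughter pairs straddle it
        newborn_pos = {c: by_id[c].position(f + 1) for c in newborn}
        proposals = []
        for j, m in enumerate(mothers):
            feas = [newborn[i] for i in range(len(newborn))
                    if np.isfinite(dist[i, j])]
            for a_i in range(len(feas)):
                for b_i in range(a_i + 1, len(feas)):
                    a, b = feas[a_i], feas[b_i]
                    mid = (newborn_pos[a] + newborn_pos[b]) / 2.0
                    cost = float(np.linalg.norm(mid - mother_pos[m]))
                    proposals.append((cost, m, a, b))
        used_mothers: set[int] = set()
        used_kids: set[int] = set()
        for cost, m, a, b in sorted(proposals):
            if m in used_mothers or a in used_kids or b in used_kids:
                continue
            parent_of[a] = m
            parent_of[b] = m
            used_mothers.add(m)
            used_kids.update((a, b))
        for j, m in enumerate(mothers):
            if m in used_mothers:
                continue
            leftover = [newborn[i] for i in range(len(newborn))
                        if np.isfinite(dist[i, j])
                        and newborn[i] not in used_kids]
            if len(leftover) == 1:
                logger.warning(
                    "mother %d at frame %d has a single candidate daughter "
                    "%d; not a division, candidate left as a new root",
                    m, f, leftover[0],
                )
    for f in sorted(starts):
        if f == 0:
            continue
        for c in starts[f]:
            if parent_of[c] is None:
                logger.warning(
                    "cell %d appears at frame %d with no candidate mother; "
                    "treated as a new root", c, f,
                )
    return _trees_from_links(by_id, parent_of)


def cell_cycle_durations(tree: LineageTree,
                         frame_interval: float = 1.0) -> list[float]:
    """Durations (hours) of every completed cycle in a tree.

    Only cells that both appear by division (have a parent) and later
    divide contribute; the duration is the span from their first to their
    last observed frame, times the frame interval.
    """
    dividing = tree.dividing_cells()
    out = []
    for cid in sorted(dividing):
        node = tree.nodes[cid]
        if node.parent_id is None:
            continue
        out.append((node.last_frame - node.first_frame) * frame_interval)
    return out


def find_sibling_pairs(trees: Iterable[LineageTree]) -> list:
    """One candidate sibling pair per division, with daughter tracks.

    Returns :class:`gutlapse.siblings.SiblingPair` objects carrying each
    daughter's full downstream observation window and (when known) its own
    division frame.
    """
    from .siblings import SiblingPair

    pairs = []
    for tree in trees:
        for div in tree.divisions:
            a, b = div.daughter_ids
            pairs.append(SiblingPair(
                division=div,
                lineage_id=tree.root,
                track_a=tree.tracks[a],
                track_b=tree.tracks[b],
                div_frame_a=tree.division_frame_of(a),
                div_frame_b=tree.division_frame_of(b),
            ))
    return pairs
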
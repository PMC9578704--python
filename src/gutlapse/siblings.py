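"""Sibling-pair classification and kinematics.

A division's two daughters form a sibling pair. Pairs are classified by
their subsequent behavior:

* **co-dividing** — both daughters divide again within the movie (the
  operational proxy for a symmetric stem-cell division); the interval
  between the two daughter divisions is recorded;
* **non-co-dividing** — exactly one daughter divides while the other is
  observed, without dividing, for at least 6 h after its sister's division
  (proxy for an asymmetric division);
* **unclassifiable** — neither divides, or the observation window is too
  short.

Kinematic read-outs follow the daughters over the first six hourly frames
after their appearance (t0..t5): 3D internuclear distance, per-step
motility with interquartile-range outlier flagging, xy movement of one
cell relative to its sister, and the out-of-plane angle between sisters in
flat stretches of epithelium.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .lineage import DivisionEvent, Track

LABEL_CODIVIDING = "co-dividing"
LABEL_NONCODIVIDING = "non-co-dividing"
LABEL_UNCLASSIFIABLE = "unclassifiable"

#: number of post-division time points analyzed (t0..t5)
DISTANCE_SERIES_LEN = 6


@dataclasses.dataclass
class SiblingPair:
    """Two daughter tracks of one division plus derived read-outs."""

    division: DivisionEvent
    lineage_id: int
    track_a: Track
    track_b: Track
    div_frame_a: int | None = None
    div_frame_b: int | None = None
    label: str | None = None
    codiv_interval_h: float | None = None
    distance_series_um: np.ndarray | None = None
    angle_deg: float | None = None

    @property
    def t0(self) -> int:
        """The daughters' shared first frame."""
        return self.division.frame + 1


def classify_pair(pair: SiblingPair, movie_end_frame: int,
                  min_quiescence_h: float = 6.0,
                  frame_interval: float = 1.0) -> str:
    """Label a sibling pair and record the co-division interval.

    The non-co-dividing call requires the quiescent sister to stay in view
    for at least ``min_quiescence_h`` hours after its sibling's division;
    a sister lost earlier leaves the pair unclassifiable.
    """
    da, db = pair.div_frame_a, pair.div_frame_b
    if da is not None and db is not None:
        pair.label = LABEL_CODIVIDING
        pair.codiv_interval_h = abs(da - db) * frame_interval
        return pair.label
    if (da is None) != (db is None):
        div_frame = da if da is not None else db
        quiet = pair.track_b if da is not None else pair.track_a
        needed = div_frame + math.ceil(min_quiescence_h / frame_interval)
        if quiet.last_frame >= needed:
            pair.label = LABEL_NONCODIVIDING
            return pair.label
    pair.label = LABEL_UNCLASSIFIABLE
    return pair.label


@dataclasses.dataclass
class KinematicsSeries:
    """Per-step 3D displacements of one track with IQR outlier flags."""

    cell_id: int
    steps: pd.DataFrame  # frame_from, frame_to, step_um, outlier

    def clean_steps(self) -> np.ndarray:
        return self.steps.loc[~self.steps["outlier"], "step_um"].to_numpy()


def iqr_outlier_flags(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag values outside [Q1 - k*IQR, Q3 + k*IQR]."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def motility_series(track: Track, frame_interval: float = 1.0) -> KinematicsSeries:
    """Per-frame 3D step lengths (µm) with interquartile outlier flags.

    Steps flagged as outliers correspond to the rare registration failures
    seen in practice; they are excluded from summaries.
    """
    pts = track.points
    if len(pts) < 2:
        raise ValueError(f"track {track.cell_id}: need >= 2 frames for motility")
    xyz = pts[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    frames = pts["frame"].to_numpy()
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    flags = iqr_outlier_flags(steps)
    df = pd.DataFrame({
        "frame_from": frames[:-1],
        "frame_to": frames[1:],
        "step_um": steps,
        "outlier": flags,
    })
    return KinematicsSeries(cell_id=track.cell_id, steps=df)


def internuclear_distance_series(pair: SiblingPair) -> np.ndarray:
    """3D sister-sister distances at t0..t5 (µm), truncated when a sister
    is lost or divides."""
    t0 = pair.t0
    last = min(pair.track_a.last_frame, pair.track_b.last_frame,
               t0 + DISTANCE_SERIES_LEN - 1)
    out = []
    for f in range(t0, last + 1):
        pa = pair.track_a.position(f)
        pb = pair.track_b.position(f)
        if pa is None or pb is None:
            break
        out.append(float(np.linalg.norm(pa - pb)))
    series = np.asarray(out)
    pair.distance_series_um = series
    return series


def relative_movement_magnitudes(pair: SiblingPair) -> np.ndarray:
    """Per-step magnitude of one sister's xy movement relative to the other.

    For each consecutive frame pair on which both sisters are observed,
    the xy displacement of B is subtracted from that of A and the
    Euclidean norm of the difference is returned. Common (tissue-level)
    motion cancels; z is excluded.
    """
    t0 = pair.t0
    last = min(pair.track_a.last_frame, pair.track_b.last_frame)
    mags = []
    for f in range(t0, last):
        pa0, pa1 = pair.track_a.position(f), pair.track_a.position(f + 1)
        pb0, pb1 = pair.track_b.position(f), pair.track_b.position(f + 1)
        if any(p is None for p in (pa0, pa1, pb0, pb1)):
            continue
        rel = (pa1 - pa0)[:2] - (pb1 - pb0)[:2]
        mags.append(float(np.linalg.norm(rel)))
    return np.asarray(mags)


@dataclasses.dataclass(frozen=True)
class AngleResult:
    angle_deg: float
    lateral_um: float
    axial_um: float


def sister_angle(pair: SiblingPair, frame: int | None = None) -> AngleResult:
    """Angle of the sister-sister axis relative to the imaging plane.

    Computed at the daughters' first shared frame unless ``frame`` is
    given: ``atan(|dz| / lateral_distance)`` in degrees, with the lateral
    and axial components returned alongside.
    """
    f = pair.t0 if frame is None else frame
    pa = pair.track_a.position(f)
    pb = pair.track_b.position(f)
    if pa is None or pb is None:
        raise ValueError(f"both sisters must be observed at frame {f}")
    delta = pa - pb
    lateral = float(np.hypot(delta[0], delta[1]))
    axial = float(abs(delta[2]))
    if lateral == 0.0 and axial == 0.0:
        raise ValueError("zero baseline: coincident sister centers")
    angle = math.degrees(math.atan2(axial, lateral))
    result = AngleResult(angle, lateral, axial)
    pair.angle_deg = angle
    return result


@dataclasses.dataclass(frozen=True)
class FlatnessResult:
    flat: bool | None
    tilt_deg: float | None
    flag: str = ""


def flatness_check(division: DivisionEvent,
                   neighbor_positions: np.ndarray,
                   tilt_max_deg: float = 10.0,
                   min_neighbors: int = 5) -> FlatnessResult:
    """Is the epithelium flat around a division site?

    Fits a least-squares plane ``z = a x + b y + c`` to neighbor nuclear
    centers (µm); the division site counts as flat when the plane's tilt
    relative to the imaging plane is below ``tilt_max_deg``.
    """
    pts = np.asarray(neighbor_positions, dtype=float)
    if len(pts) < min_neighbors:
        return FlatnessResult(None, None, "insufficient neighbors")
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coeffs, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    tilt = math.degrees(math.atan(math.hypot(coeffs[0], coeffs[1])))
    return FlatnessResult(tilt < tilt_max_deg, tilt)


@dataclasses.dataclass(frozen=True)
class DifferentiationResult:
    area_ratio: float
    gfp_ratio: float
    differentiating: bool
    flags: tuple[str, ...] = ()


def differentiation_flags(track: Track, t_ref: int, t_cmp: int,
                          area_fold_min: float = 1.5,
                          gfp_fold_max: float = 0.5) -> DifferentiationResult:
    """Nuclear growth + GFP loss call for one cell between two frames.

    A cell whose nuclear area grows by at least ``area_fold_min`` while
    its GFP falls to at most ``gfp_fold_max`` of the reference value is
    flagged as differentiating (enteroblast-to-enterocyte transition).
    With zero reference GFP the ratio is undefined and the call falls back
    to area alone, with a warning flag.
    """
    ref = track.at(t_ref)
    cmp_ = track.at(t_cmp)
    if ref is None or cmp_ is None:
        raise ValueError("track must be observed at both frames")
    area_ratio = float(cmp_["area_um2"] / ref["area_um2"])
    flags: list[str] = []
    if ref["gfp"] == 0:
        gfp_ratio = float("nan")
        flags.append("zero-reference-gfp")
        flag = area_ratio >= area_fold_min
    else:
        gfp_ratio = float(cmp_["gfp"] / ref["gfp"])
        flag = area_ratio >= area_fold_min and gfp_ratio <= gfp_fold_max
    return DifferentiationResult(area_ratio, gfp_ratio, bool(flag), tuple(flags))


def pair_table(pairs: Sequence[SiblingPair],
               frame_interval: float = 1.0) -> pd.DataFrame:
    """Flatten analyzed pairs into the report table schema."""
    rows = []
    for i, p in enumerate(pairs, start=1):
        dist = p.distance_series_um
        if dist is None:
            dist = internuclear_distance_series(p)
        row = {
            "division_id": i,
            "lineage_id": p.lineage_id,
            "mother_id": p.division.mother_id,
            "label": p.label if p.label is not None else LABEL_UNCLASSIFIABLE,
            "codiv_interval_h": p.codiv_interval_h,
        }
        for k in range(DISTANCE_SERIES_LEN):
            row[f"dist_t{k}"] = dist[k] if k < len(dist) else np.nan
        row["angle_deg"] = p.angle_deg
        row["flat_flag"] = p.division.flat_flag
        rows.append(row)
    return pd.DataFrame(rows)
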
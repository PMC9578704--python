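"""Local drift registration of explant time-lapse movies.

The explanted epithelium slowly drifts and deforms under the agarose, so a
single global transform is not enough. The movie is tiled once (at the
first frame) into overlapping ROIs; each ROI's translation to the next
frame is estimated by normalized (Pearson) cross-correlation at integer
pixel resolution, and per-ROI shifts are composed cumulatively so that any
frame-t coordinate can be mapped back into the frame-0 reference.

No rotation, scaling, sub-pixel refinement, or non-rigid warping is
attempted.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import match_template

#: score written for degenerate (zero-variance) patches
DEGENERATE_SCORE = float("nan")


class RegistrationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class RoiGrid:
    """Overlapping ROI tiling of a frame; boxes are half-open (y0,x0,y1,x1)."""

    roi_size: int
    overlap: int
    frame_shape: tuple[int, int]
    boxes: tuple[tuple[int, int, int, int], ...]

    def containing(self, y: float, x: float) -> list[int]:
        return [
            i for i, (y0, x0, y1, x1) in enumerate(self.boxes)
            if y0 <= y < y1 and x0 <= x < x1
        ]


def _starts(extent: int, roi_size: int, stride: int) -> list[int]:
    starts = list(range(0, extent - roi_size + 1, stride))
    last = extent - roi_size
    if starts[-1] != last:
        starts.append(last)  # final box shifted inward to stay in frame
    return starts


def tile_rois(frame_height: int, frame_width: int,
              roi_size: int, overlap: int) -> RoiGrid:
    """Tile a frame into overlapping ROIs at stride ``roi_size - overlap``."""
    if roi_size > min(frame_height, frame_width):
        raise ValueError("roi_size exceeds frame dimensions")
    if roi_size == frame_height == frame_width:
        boxes = [(0, 0, roi_size, roi_size)]
        return RoiGrid(roi_size, overlap, (frame_height, frame_width), tuple(boxes))
    if not 0 < overlap < roi_size:
        raise ValueError("overlap must satisfy 0 < overlap < roi_size")
    stride = roi_size - overlap
    boxes = [
        (y0, x0, y0 + roi_size, x0 + roi_size)
        for y0 in _starts(frame_height, roi_size, stride)
        for x0 in _starts(frame_width, roi_size, stride)
    ]
    return RoiGrid(roi_size, overlap, (frame_height, frame_width), tuple(boxes))


@dataclasses.dataclass(frozen=True)
class ShiftEstimate:
    dy: int
    dx: int
    score: float
    degenerate: bool = False


def estimate_shift(reference_patch: np.ndarray, next_frame: np.ndarray,
                   max_shift: int) -> ShiftEstimate:
    """Integer shift of ``reference_patch`` content within ``next_frame``.

    ``next_frame`` is a search region at least ``2*max_shift`` larger than
    the patch in both dimensions; the patch's nominal (zero-shift) position
    is its centered placement. The returned shift maximizes the normalized
    cross-correlation (zero-mean, unit-variance, i.e. Pearson r in
    [-1, 1]); ties are broken by smallest Euclidean shift magnitude, then
    lexicographically by (dy, dx). A constant reference patch is flagged
    degenerate and reported as shift (0, 0) with an undefined score.
    """
    patch = np.asarray(reference_patch, dtype=float)
    region = np.asarray(next_frame, dtype=float)
    oy = (region.shape[0] - patch.shape[0]) // 2
    ox = (region.shape[1] - patch.shape[1]) // 2
    if oy < max_shift or ox < max_shift:
        raise ValueError("search region too small for the requested max_shift")
    if float(patch.std()) == 0.0:
        return ShiftEstimate(0, 0, DEGENERATE_SCORE, degenerate=True)
    response = match_template(region, patch)
    window = response[oy - max_shift: oy + max_shift + 1,
                      ox - max_shift: ox + max_shift + 1]
    window = np.where(np.isfinite(window), window, -2.0)
    best = float(window.max())
    cand = np.argwhere(window >= best - 1e-9) - max_shift
    dy, dx = min(map(tuple, cand), key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]))
    score = float(window[dy + max_shift, dx + max_shift])
    return ShiftEstimate(int(dy), int(dx), min(max(score, -1.0), 1.0))


@dataclasses.dataclass
class ShiftField:
    """Per-ROI, per-frame-pair integer shifts plus their composition.

    Row ``(roi, frame)`` holds the estimated translation of the scene
    content inside that ROI from ``frame`` to ``frame + 1``; cumulative
    sums map frame-t coordinates back to the frame-0 reference.
    """

    grid: RoiGrid
    shifts: pd.DataFrame  # roi, frame, dy, dx, score, flag

    @property
    def n_frames(self) -> int:
        return int(self.shifts["frame"].max()) + 2

    def cumulative(self) -> np.ndarray:
        """(n_rois, n_frames, 2) array: content offset of frame t vs frame 0."""
        n_rois = len(self.grid.boxes)
        cum = np.zeros((n_rois, self.n_frames, 2))
        for row in self.shifts.itertuples(index=False):
            cum[row.roi, row.frame + 1] = (row.dy, row.dx)
        return np.cumsum(cum, axis=1)

    def _score(self, roi: int, step: int) -> float:
        sel = self.shifts[(self.shifts["roi"] == roi) & (self.shifts["frame"] == step)]
        if sel.empty:
            return -np.inf
        v = float(sel["score"].iloc[0])
        return v if np.isfinite(v) else -np.inf

    def transform_points(self, frames: np.ndarray, ys: np.ndarray,
                         xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel coordinates observed at ``frames`` into frame-0 space.

        Each point uses the ROI containing it; when several boxes contain
        it, the one with the highest correlation score at the relevant
        transition wins.
        """
        cum = self.cumulative()
        last_step = self.n_frames - 2
        out_y = np.empty(len(ys), dtype=float)
        out_x = np.empty(len(xs), dtype=float)
        for i, (t, y, x) in enumerate(zip(frames, ys, xs)):
            boxes = self.grid.containing(y, x)
            if not boxes:
                raise ValueError(f"point ({y}, {x}) outside every ROI")
            step = min(max(int(t) - 1, 0), last_step)
            roi = max(boxes, key=lambda b: self._score(b, step))
            dy, dx = cum[roi, int(t)]
            out_y[i] = y - dy
            out_x[i] = x - dx
        return out_y, out_x

    def to_csv(self, path: str | Path) -> None:
        self.shifts.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path, grid: RoiGrid) -> "ShiftField":
        return cls(grid, pd.read_csv(path))


def _project(stack: np.ndarray, channel: int) -> np.ndarray:
    """Reduce a movie to (t, y, x) by channel selection and z max-projection."""
    if stack.ndim == 3:
        return np.asarray(stack, dtype=float)
    if stack.ndim == 4:          # (t, z, y, x)
        return stack.max(axis=1).astype(float)
    if stack.ndim == 5:          # (t, z, c, y, x)
        return stack[:, :, channel].max(axis=1).astype(float)
    raise ValueError(f"unsupported stack shape {stack.shape}")


def _neighbor_indices(grid: RoiGrid, roi: int) -> list[int]:
    y0, x0, y1, x1 = grid.boxes[roi]
    cy, cx = (y0 + y1) / 2, (x0 + x1) / 2
    stride = max(grid.roi_size - grid.overlap, 1)
    out = []
    for j, (b0, a0, b1, a1) in enumerate(grid.boxes):
        if j == roi:
            continue
        if abs((b0 + b1) / 2 - cy) <= 1.5 * stride and abs((a0 + a1) / 2 - cx) <= 1.5 * stride:
            out.append(j)
    return out


def register_movie(stack: np.ndarray, grid: RoiGrid, max_shift: int,
                   channel: int = 0) -> ShiftField:
    """Estimate per-ROI frame-to-frame shifts over a whole movie.

    Shifts are estimated on the z maximum-intensity projection of the
    chosen channel. Degenerate (zero-variance) ROIs are flagged and their
    shift repaired with the median shift of neighboring ROIs in the same
    frame pair; a frame pair in which more than half of the ROIs are
    degenerate aborts the registration.
    """
    movie = _project(stack, channel)
    if movie.shape[0] < 2:
        raise ValueError("need at least two frames to register")
    rows = []
    bad_frames = []
    for t in range(movie.shape[0] - 1):
        padded = np.pad(movie[t + 1], max_shift, mode="edge")
        frame_rows = []
        for roi, (y0, x0, y1, x1) in enumerate(grid.boxes):
            patch = movie[t, y0:y1, x0:x1]
            region = padded[y0:y1 + 2 * max_shift, x0:x1 + 2 * max_shift]
            est = estimate_shift(patch, region, max_shift)
            frame_rows.append([roi, t, est.dy, est.dx, est.score, est.degenerate])
        n_bad = sum(r[5] for r in frame_rows)
        if n_bad * 2 > len(frame_rows):
            bad_frames.append(t)
        for r in frame_rows:
            if r[5]:  # repair from neighbors
                neigh = [
                    frame_rows[j] for j in _neighbor_indices(grid, r[0])
                    if not frame_rows[j][5]
                ]
                if neigh:
                    r[2] = int(np.median([n[2] for n in neigh]))
                    r[3] = int(np.median([n[3] for n in neigh]))
        rows.extend(frame_rows)
    if bad_frames:
        raise RegistrationError(
            f"more than half of the ROIs are degenerate in frame pairs {bad_frames}"
        )
    shifts = pd.DataFrame(rows, columns=["roi", "frame", "dy", "dx", "score", "flag"])
    return ShiftField(grid=grid, shifts=shifts)
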
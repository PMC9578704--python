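"""Agent-based generator of midgut progenitor lineages and synthetic movies.

The simulator produces the statistical structure the downstream analysis
assumes, with a recoverable ground truth:

* founder cells divide with cycle times drawn from a truncated normal
  (mean 8 h, SD 2.76 h by default);
* a division is "symmetric-like" with probability ``p_symmetric``: both
  daughters re-divide and actively move apart with opposed directional
  velocities for five frames; otherwise one daughter re-divides while the
  other stays quiescent, grows its nucleus and loses GFP (differentiation);
* every cell performs an isotropic random walk in the epithelial plane with
  small z jitter;
* nuclear GFP switches on asynchronously (uniform onset, by default between
  8 h and 36 h), rises to a plateau and dims slowly through photobleaching;
* an optional slow global drift is applied at render time for registration
  tests.

``simulate_lineages`` returns the ground-truth tables; ``render_movie``
rasterizes nuclei as Gaussian blobs into a (t, z, channel, y, x) stack with
optional Poisson noise.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

TRACKS_COLUMNS = [
    "cell_id", "parent_id", "frame", "x_um", "y_um", "z_um",
    "area_um2", "gfp", "fate",
]
PAIRS_COLUMNS = [
    "division_id", "lineage_id", "mother_id", "daughter_a", "daughter_b",
    "division_frame", "first_frame", "label",
]

#: frames of directional separation given to symmetric-like daughters;
#: matches the six-frame (t0..t5) analysis window of the sibling kinematics.
SEPARATION_FRAMES = 5
#: resting nuclear area of a progenitor, µm² (~4 µm diameter nucleus)
BASE_AREA_UM2 = 12.0
#: plateau nuclear GFP level, arbitrary units
GFP_PLATEAU = 100.0
#: hours for GFP to rise from onset to plateau
GFP_RISE_H = 4.0
#: half-life (hours) of GFP in differentiating (quiescent) daughters
DIFF_GFP_HALFLIFE_H = 24.0
#: initial half-separation of newborn daughters, µm
DAUGHTER_OFFSET_UM = 2.5
#: hard-core exclusion distance between nuclear centers, µm; newborn
#: sisters (5 µm apart) are the closest pair the model allows to persist
MIN_NUCLEAR_DISTANCE_UM = 3.5

FATE_DIVIDING = "re-dividing"
FATE_QUIESCENT = "quiescent"
LABEL_SYMMETRIC = "symmetric-like"
LABEL_ASYMMETRIC = "asymmetric-like"


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Knobs of the lineage simulation; every rate is per the stated unit.

    ``cycle_mean``/``cycle_sd`` are the cell-cycle moments in hours;
    ``p_symmetric`` the probability a division yields two re-dividing
    daughters; ``motility_step_mean`` the mean isotropic random-walk step
    per frame (µm); ``separation_speed`` the directional speed imposed on
    symmetric-like daughters (µm/frame); ``gfp_onset_range`` the uniform
    onset window in hours post induction; ``bleach_rate`` the fractional
    GFP loss per imaged frame; ``differentiation_area_growth`` the nuclear
    area fold-change over 48 h in differentiating daughters.
    """

    n_founders: int = 20
    t_max: float = 48.0
    frame_interval: float = 1.0
    cycle_mean: float = 8.0
    cycle_sd: float = 2.76
    p_symmetric: float = 0.3
    motility_step_mean: float = 0.2
    separation_speed: float = 1.5
    gfp_onset_range: tuple[float, float] = (8.0, 36.0)
    bleach_rate: float = 0.002
    differentiation_area_growth: float = 2.0
    field_size_um: tuple[float, float] = (200.0, 200.0)
    stack_depth_um: float = 45.0
    z_jitter_um: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        nonneg = (
            "cycle_mean", "cycle_sd", "motility_step_mean",
            "separation_speed", "bleach_rate", "z_jitter_um",
        )
        for name in nonneg:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not math.isfinite(self.t_max) or not math.isfinite(self.frame_interval):
            raise ValueError("t_max and frame_interval must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.t_max < self.frame_interval:
            raise ValueError("t_max shorter than one frame interval")
        if not 0.0 <= self.p_symmetric <= 1.0:
            raise ValueError("p_symmetric must lie in [0, 1]")
        lo, hi = self.gfp_onset_range
        if lo > hi:
            raise ValueError("gfp_onset_range low must be <= high")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if self.differentiation_area_growth < 1:
            raise ValueError("differentiation_area_growth is a fold >= 1")

    @property
    def n_frames(self) -> int:
        """Index of the last frame (frames run 0..n_frames)."""
        return int(round(self.t_max / self.frame_interval))


@dataclasses.dataclass
class SimScene:
    """Ground-truth output of one simulation.

    ``truth_tracks`` has one row per cell per frame (schema
    :data:`TRACKS_COLUMNS`); ``truth_pairs`` one row per division (schema
    :data:`PAIRS_COLUMNS`); ``drift`` is the per-frame global translation
    (dy, dx) in µm applied only at render time.
    """

    params: SimulationParams
    truth_tracks: pd.DataFrame
    truth_pairs: pd.DataFrame
    drift: np.ndarray

    def with_linear_drift(self, per_frame: tuple[float, float]) -> "SimScene":
        """Return a copy whose render-time drift grows linearly per frame."""
        t = np.arange(self.params.n_frames + 1, dtype=float)
        drift = np.stack([t * per_frame[0], t * per_frame[1]], axis=1)
        return dataclasses.replace(self, drift=drift)

    def completed_cycle_durations(self) -> np.ndarray:
        """Cycle durations (hours) recomputed from the truth tables.

        A completed cycle belongs to a cell that was born by division
        (has a parent) and later divided itself; its duration is the span
        from first to last observed frame, times the frame interval.
        """
        tracks = self.truth_tracks
        spans = tracks.groupby("cell_id")["frame"].agg(["min", "max"])
        has_parent = set(
            tracks.loc[tracks["parent_id"].notna(), "cell_id"].unique()
        )
        mothers = set(self.truth_pairs["mother_id"])
        ids = sorted(has_parent & mothers)
        fi = self.params.frame_interval
        return np.array(
            [(spans.loc[i, "max"] - spans.loc[i, "min"]) * fi for i in ids]
        )

    def write_tracks_csv(self, path: str | Path) -> None:
        self.truth_tracks.to_csv(path, index=False, float_format="%.6g")

    def write_pairs_csv(self, path: str | Path) -> None:
        self.truth_pairs.to_csv(path, index=False)

    def write_meta_json(self, path: str | Path) -> None:
        meta = {
            "params": dataclasses.asdict(self.params),
            "drift_um": self.drift.tolist(),
        }
        Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


@dataclasses.dataclass
class _Cell:
    cid: int
    parent: int | None
    lineage: int
    birth: int
    fate: str
    pos: np.ndarray            # (x, y) µm
    z: float                   # µm
    onset_h: float
    cycle_frames: int | None   # None for quiescent cells
    sep_vel: np.ndarray | None = None
    sep_left: int = 0
    area: float = BASE_AREA_UM2
    bleach: float = 1.0
    diff_gfp: float = 1.0

    @property
    def last_frame_if_dividing(self) -> int | None:
        if self.cycle_frames is None:
            return None
        return self.birth + self.cycle_frames


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([math.cos(theta), math.sin(theta)])


def _reflect(value: float, low: float, high: float) -> float:
    # reflecting walls; one bounce suffices for the small steps simulated
    if value < low:
        value = low + (low - value)
    if value > high:
        value = high - (value - high)
    return min(max(value, low), high)


def _resolve_overlaps(cells: list[_Cell], params: SimulationParams) -> None:
    """Push apart nuclei closer than the hard-core exclusion distance.

    Nuclei are solid bodies: two centers cannot coexist closer than
    roughly a nuclear diameter. A few relaxation sweeps displace each
    member of an overlapping pair symmetrically along their 3D separation
    axis; ties (coincident centers) break along x by cell id order.
    """
    d_min = MIN_NUCLEAR_DISTANCE_UM
    if len(cells) < 2 or d_min <= 0:
        return
    fx, fy = params.field_size_um
    for _ in range(3):
        pos = np.array([[c.pos[0], c.pos[1], c.z] for c in cells])
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta ** 2).sum(axis=2))
        iu = np.triu_indices(len(cells), k=1)
        close = dist[iu] < d_min
        if not close.any():
            return
        for i, j in zip(iu[0][close], iu[1][close]):
            v = pos[i] - pos[j]
            d = float(np.linalg.norm(v))
            v = v / d if d > 0 else np.array([1.0, 0.0, 0.0])
            push = (d_min - d) / 2.0
            for cell, sign in ((cells[i], 1.0), (cells[j], -1.0)):
                cell.pos = cell.pos + sign * push * v[:2]
                cell.z = _reflect(cell.z + sign * push * v[2],
                                  0.0, params.stack_depth_um)
                cell.pos[0] = _reflect(cell.pos[0], 0.0, fx)
                cell.pos[1] = _reflect(cell.pos[1], 0.0, fy)


def simulate_lineages(params: SimulationParams) -> SimScene:
    """Run the forward agent-based simulation and return its ground truth.

    Identical ``params`` (including ``seed``) give a byte-identical scene.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    T = params.n_frames
    fi = params.frame_interval
    # E[|step|] of an isotropic 2D Gaussian is sigma * sqrt(pi/2)
    sigma_step = params.motility_step_mean * math.sqrt(2.0 / math.pi)
    sigma_z = params.z_jitter_um
    fx, fy = params.field_size_um
    diff_growth_per_frame = params.differentiation_area_growth ** (fi / 48.0)
    diff_gfp_decay = 0.5 ** (fi / DIFF_GFP_HALFLIFE_H)

    def draw_cycle() -> int:
        hours = rng.normal(params.cycle_mean, params.cycle_sd)
        return max(1, int(round(hours / fi)))

    def draw_onset(mother_onset: float | None) -> float:
        onset = rng.uniform(*params.gfp_onset_range)
        if mother_onset is not None:
            # transgene induction is monotone within a lineage
            onset = min(onset, mother_onset)
        return onset

    next_id = 1
    active: list[_Cell] = []
    for _ in range(params.n_founders):
        pos = np.array([
            rng.uniform(5.0, fx - 5.0),
            rng.uniform(5.0, fy - 5.0),
        ])
        z = rng.uniform(10.0, max(10.0, params.stack_depth_um - 10.0))
        active.append(_Cell(
            cid=next_id, parent=None, lineage=next_id, birth=0,
            fate=FATE_DIVIDING, pos=pos, z=z,
            onset_h=draw_onset(None), cycle_frames=draw_cycle(),
        ))
        next_id += 1

    rows: list[tuple] = []
    pairs: list[tuple] = []
    division_id = 0
    for t in range(T + 1):
        for cell in active:
            if t > cell.birth:
                step = rng.normal(0.0, sigma_step, 2) if sigma_step > 0 else np.zeros(2)
                if cell.sep_left > 0 and cell.sep_vel is not None:
                    step = step + cell.sep_vel
                    cell.sep_left -= 1
                cell.pos = cell.pos + step
                cell.pos[0] = _reflect(cell.pos[0], 0.0, fx)
                cell.pos[1] = _reflect(cell.pos[1], 0.0, fy)
                if sigma_z > 0:
                    cell.z = _reflect(
                        cell.z + rng.normal(0.0, sigma_z), 0.0, params.stack_depth_um
                    )
                if cell.fate == FATE_QUIESCENT:
                    cell.area *= diff_growth_per_frame
                    cell.diff_gfp *= diff_gfp_decay
        _resolve_overlaps(active, params)
        for cell in active:
            t_h = t * fi
            if t_h < cell.onset_h:
                gfp = 0.0
            else:
                rise = min(1.0, (t_h - cell.onset_h) / GFP_RISE_H) if GFP_RISE_H > 0 else 1.0
                gfp = GFP_PLATEAU * rise * cell.bleach * cell.diff_gfp
                cell.bleach *= (1.0 - params.bleach_rate)
            rows.append((
                cell.cid, cell.parent, t,
                float(cell.pos[0]), float(cell.pos[1]), float(cell.z),
                float(cell.area), float(gfp), cell.fate,
            ))

        survivors: list[_Cell] = []
        for cell in active:
            last = cell.last_frame_if_dividing
            if last is not None and last == t and t < T:
                axis = _unit_vector(rng)
                symmetric = rng.random() < params.p_symmetric
                daughters = []
                for sign in (1.0, -1.0):
                    d = _Cell(
                        cid=next_id, parent=cell.cid, lineage=cell.lineage,
                        birth=t + 1, fate=FATE_DIVIDING,
                        pos=cell.pos + sign * DAUGHTER_OFFSET_UM * axis,
                        z=cell.z,
                        onset_h=draw_onset(cell.onset_h),
                        cycle_frames=None,
                    )
                    d.pos[0] = _reflect(d.pos[0], 0.0, fx)
                    d.pos[1] = _reflect(d.pos[1], 0.0, fy)
                    next_id += 1
                    daughters.append(d)
                if symmetric:
                    for sign, d in zip((1.0, -1.0), daughters):
                        d.cycle_frames = draw_cycle()
                        d.sep_vel = sign * params.separation_speed * axis
                        d.sep_left = SEPARATION_FRAMES
                    label = LABEL_SYMMETRIC
                else:
                    divider = int(rng.integers(0, 2))
                    daughters[divider].cycle_frames = draw_cycle()
                    daughters[1 - divider].fate = FATE_QUIESCENT
                    label = LABEL_ASYMMETRIC
                division_id += 1
                pairs.append((
                    division_id, cell.lineage, cell.cid,
                    daughters[0].cid, daughters[1].cid, t, t + 1, label,
                ))
                survivors.extend(daughters)
            elif last is None or last > t:
                survivors.append(cell)
        active = survivors

    tracks = pd.DataFrame(rows, columns=TRACKS_COLUMNS)
    tracks["parent_id"] = tracks["parent_id"].astype("Int64")
    tracks = tracks.sort_values(["cell_id", "frame"], kind="stable").reset_index(drop=True)
    truth_pairs = pd.DataFrame(pairs, columns=PAIRS_COLUMNS)
    drift = np.zeros((T + 1, 2))
    return SimScene(params=params, truth_tracks=tracks,
                    truth_pairs=truth_pairs, drift=drift)


def render_movie(
    scene: SimScene,
    pixel_size: float,
    z_step: float,
    noise_level: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Rasterize a scene into a (t, z, channel, y, x) stack.

    Each nucleus becomes an anisotropic Gaussian blob (xy sigma = half the
    nuclear radius, z sigma twice that) whose peak amplitude is the cell's
    GFP level on channel 0; channel 1 carries a constant-amplitude nuclear
    (DAPI-like) signal. The scene's per-frame drift is added before
    rasterization; positions pushed outside the field are clipped and
    counted. With ``noise_level > 0`` the stack is Poisson-resampled with
    that additive background mean.

    Returns ``(stack, meta)`` where ``meta`` holds the information needed
    to invert pixel coordinates back to µm.
    """
    if pixel_size <= 0 or z_step <= 0:
        raise ValueError("pixel_size and z_step must be positive")
    params = scene.params
    T = params.n_frames
    ny = int(math.ceil(params.field_size_um[1] / pixel_size))
    nx = int(math.ceil(params.field_size_um[0] / pixel_size))
    nz = int(math.floor(params.stack_depth_um / z_step)) + 1
    stack = np.zeros((T + 1, nz, 2, ny, nx))
    z_centers = np.arange(nz) * z_step
    clipped = 0

    by_frame = scene.truth_tracks.groupby("frame")
    for t in range(T + 1):
        if t not in by_frame.groups:
            continue
        dy, dx = scene.drift[t]
        for row in by_frame.get_group(t).itertuples(index=False):
            cx = (row.x_um + dx) / pixel_size
            cy = (row.y_um + dy) / pixel_size
            if not (0.0 <= cx <= nx - 1 and 0.0 <= cy <= ny - 1):
                clipped += 1
                cx = min(max(cx, 0.0), nx - 1.0)
                cy = min(max(cy, 0.0), ny - 1.0)
            radius_um = math.sqrt(row.area_um2 / math.pi)
            sig_xy = max(0.8, 0.5 * radius_um / pixel_size)  # px
            sig_z = 2.0 * 0.5 * radius_um                    # µm
            half = int(math.ceil(3.0 * sig_xy))
            y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
            x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
            yy = np.arange(y0, y1)
            xx = np.arange(x0, x1)
            gy = np.exp(-0.5 * ((yy - cy) / sig_xy) ** 2)
            gx = np.exp(-0.5 * ((xx - cx) / sig_xy) ** 2)
            blob = np.outer(gy, gx)
            wz = np.exp(-0.5 * ((z_centers - row.z_um) / sig_z) ** 2)
            for zi in np.nonzero(wz > 1e-4)[0]:
                stack[t, zi, 0, y0:y1, x0:x1] += row.gfp * wz[zi] * blob
                stack[t, zi, 1, y0:y1, x0:x1] += GFP_PLATEAU * wz[zi] * blob

    if clipped:
        logger.warning("render_movie: %d cell positions clipped to the field", clipped)
    if noise_level > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        stack = rng.poisson(stack + noise_level).astype(float)
    meta = {
        "pixel_size_um": pixel_size,
        "z_step_um": z_step,
        "noise_level": noise_level,
        "axes": "TZCYX",
        "n_clipped": clipped,
    }
    return stack, meta


def write_movie_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write a (t, z, channel, y, x) stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), stack.astype(np.float32), metadata={"axes": "TZCYX"})


def read_movie_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["parent_id"] = df["parent_id"].astype("Int64")
    return df
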
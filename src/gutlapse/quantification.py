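"""Per-cell and per-organ intensity and morphology measurements.

Covers three read-outs:

* dual-channel Otsu quantification — GFP and nuclear (DAPI) channels are
  each thresholded by Otsu's method, the overlap of the binary masks is
  labeled into nuclei, and per-cell mean GFP is averaged into a per-organ
  value;
* nuclear GFP with local-background adjustment — the median of a square
  window (50 µm by default) around the nucleus, nuclear pixels excluded,
  is subtracted from the raw mean;
* the cell-death (NucGreen) daily time-series — each day's image is
  divided by its median pixel value (cancelling global gain changes), the
  masked sum is taken, and the series is normalized to its first day.

Nuclear area is the shoelace area of a sub-pixel outline polygon scaled by
the squared pixel size.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Polygon

DEFAULT_MIN_AREA_PX = 20
#: minimum usable pixels for a trustworthy local background estimate
MIN_BACKGROUND_PIXELS = 100


class DegenerateHistogramError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CellOutline:
    """Manual outline of one nucleus at its most in-focus z-slice."""

    cell_id: int
    frame: int
    z_index: int
    vertices: np.ndarray  # (n, 2) sub-pixel (x, y)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("outline needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


@dataclasses.dataclass(frozen=True)
class IntensityRecord:
    cell_id: int
    frame: int
    area_um2: float
    gfp_raw: float
    gfp_background: float
    gfp_adjusted: float
    flags: str = ""


def _as_histogram(histogram) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(histogram, Mapping):
        levels = np.array(sorted(histogram), dtype=float)
        counts = np.array([histogram[k] for k in sorted(histogram)], dtype=float)
    elif isinstance(histogram, tuple) and len(histogram) == 2:
        levels = np.asarray(histogram[0], dtype=float)
        counts = np.asarray(histogram[1], dtype=float)
        order = np.argsort(levels)
        levels, counts = levels[order], counts[order]
    else:
        counts = np.asarray(histogram, dtype=float)
        levels = np.arange(len(counts), dtype=float)
    return levels, counts


def otsu_threshold(histogram) -> float:
    """Otsu's threshold of an intensity histogram.

    ``histogram`` may be a ``{level: count}`` mapping, a ``(levels,
    counts)`` pair, or a 1D count array indexed by level. Returns the level
    maximizing the between-class variance when pixels with value <= level
    form the lower class; on ties the lowest such level wins.
    """
    levels, counts = _as_histogram(histogram)
    keep = counts > 0
    levels, counts = levels[keep], counts[keep]
    if len(levels) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied levels")
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    cum_mass = np.cumsum(levels * counts)[:-1]
    mu0 = cum_mass / w0
    mu1 = (cum_mass[-1] + levels[-1] * counts[-1] - cum_mass) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    return float(levels[int(np.argmax(sigma_b))])


def otsu_threshold_image(image: np.ndarray, bins: int = 256) -> float:
    """Otsu threshold of an image, histogrammed at its occupied levels.

    Images with up to 4096 distinct values are treated exactly; denser
    images are binned and the threshold is the corresponding bin center.
    """
    img = np.asarray(image)
    values, counts = np.unique(img, return_counts=True)
    if len(values) <= 4096:
        return otsu_threshold((values.astype(float), counts.astype(float)))
    counts, edges = np.histogram(img.ravel(), bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return otsu_threshold((centers, counts.astype(float)))


def overlap_mask(gfp_image: np.ndarray, dapi_image: np.ndarray,
                 min_area_px: int = DEFAULT_MIN_AREA_PX) -> np.ndarray:
    """Label nuclei as the overlap of per-channel Otsu masks.

    Both channels are thresholded independently; the logical AND of the
    suprathreshold masks is labeled with 8-connectivity and components
    smaller than ``min_area_px`` are dropped. Labels are renumbered
    consecutively from 1.
    """
    gfp = np.asarray(gfp_image, dtype=float)
    dapi = np.asarray(dapi_image, dtype=float)
    if gfp.shape != dapi.shape:
        raise ValueError("channel images must share a shape")
    mask = (gfp > otsu_threshold_image(gfp)) & (dapi > otsu_threshold_image(dapi))
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.nonzero(sizes >= min_area_px)[0] + 1
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def mean_gfp_per_gut(gfp_image: np.ndarray,
                     mask: np.ndarray) -> tuple[pd.Series, float]:
    """Per-cell mean GFP and their unweighted per-organ average."""
    labels = np.asarray(mask)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("no cells: overlap mask is empty")
    means = ndi.mean(np.asarray(gfp_image, dtype=float), labels, index=ids)
    per_cell = pd.Series(means, index=pd.Index(ids, name="cell"), name="mean_gfp")
    return per_cell, float(per_cell.mean())


@dataclasses.dataclass(frozen=True)
class BackgroundAdjusted:
    adjusted: float
    background: float
    flags: tuple[str, ...] = ()


def local_background_adjust(
    raw_mean: float,
    image: np.ndarray,
    center: tuple[float, float],
    window_um: float,
    pixel_size: float,
    exclusion_mask: np.ndarray | None = None,
) -> BackgroundAdjusted:
    """Subtract the local median background from a raw nuclear mean.

    The background is the median of pixels in the axis-aligned square
    window of side ``window_um`` centered on ``center`` (y, x in pixels),
    excluding pixels of ``exclusion_mask`` (the nuclear mask). The
    adjusted value is floored at zero. A window clipped at the image
    border to fewer than 100 usable pixels is flagged ``"border"``.
    """
    img = np.asarray(image, dtype=float)
    half = int(round(window_um / (2.0 * pixel_size)))
    cy, cx = int(round(center[0])), int(round(center[1]))
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    clipped = y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, img.shape[0]), min(x1, img.shape[1])
    window = img[y0:y1, x0:x1]
    if exclusion_mask is not None:
        usable = window[~np.asarray(exclusion_mask, dtype=bool)[y0:y1, x0:x1]]
    else:
        usable = window.ravel()
    if usable.size == 0:
        raise ValueError("background window has no usable pixels")
    flags: list[str] = []
    if usable.size < MIN_BACKGROUND_PIXELS:
        flags.append("border" if clipped else "sparse-window")
    background = float(np.median(usable))
    return BackgroundAdjusted(
        adjusted=max(0.0, float(raw_mean) - background),
        background=background,
        flags=tuple(flags),
    )


def nuclear_area(outline: CellOutline | np.ndarray, pixel_size: float) -> float:
    """Shoelace area of a sub-pixel outline polygon, in µm²."""
    vertices = outline.vertices if isinstance(outline, CellOutline) else np.asarray(outline, float)
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError("outline polygon is self-intersecting")
    return float(poly.area) * pixel_size ** 2


def polygon_to_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an (x, y) polygon into a boolean mask of ``shape``."""
    from skimage.draw import polygon as sk_polygon

    v = np.asarray(vertices, dtype=float)
    rr, cc = sk_polygon(v[:, 1], v[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def nucgreen_timeseries(daily_stacks: Sequence[np.ndarray],
                        organ_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Daily cell-death signal, median-normalized and scaled to day 0.

    Each day's stack is max-projected (if 3D), divided by its median pixel
    value to cancel background/gain changes, and summed inside the organ
    mask; the resulting series is divided by its first value, so the
    output starts at exactly 1.0.
    """
    if len(daily_stacks) != len(organ_masks):
        raise ValueError("need one mask per daily stack")
    if len(daily_stacks) == 0:
        raise ValueError("empty series")
    values = []
    for stack, mask in zip(daily_stacks, organ_masks):
        img = np.asarray(stack, dtype=float)
        if img.ndim == 3:
            img = img.max(axis=0)
        med = float(np.median(img))
        if med == 0.0:
            raise ValueError("degenerate image: zero median pixel value")
        values.append(float((img / med)[np.asarray(mask, dtype=bool)].sum()))
    series = np.asarray(values)
    if series[0] == 0.0:
        raise ValueError("degenerate series: zero masked sum at t0")
    return series / series[0]


def records_to_csv(records: Iterable[IntensityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.cell_id, r.frame, r.area_um2, r.gfp_raw, r.gfp_background,
          r.gfp_adjusted, r.flags) for r in records],
        columns=["cell_id", "frame", "area_um2", "gfp_raw", "gfp_bg",
                 "gfp_adj", "flags"],
    )
    df.to_csv(path, index=False, float_format="%.6g")
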
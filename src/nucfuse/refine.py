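"""Precise boundary refinement by 2-means clustering in the (I, B) plane.

Each rough nucleus is cut out of the fused image into a window whose
surroundings are replaced by the mean intensity of the rough boundary; the
window pixels are then clustered on (scaled intensity, scaled rough-mask
membership) and the cluster carrying the rough mask becomes the refined
foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import as_binary


@dataclass
class RefineParams:
    w2: float = 0.4
    margin: int | None = None  # None: 25% of bbox diagonal, min 5 px

    def __post_init__(self) -> None:
        if self.w2 < 0:
            raise ValueError("w2 must be >= 0")


@dataclass
class NucleusWindow:
    bounds: tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open
    composite: np.ndarray
    rough_mask: np.ndarray
    boundary_mean: float


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: mask pixels with a background 4-neighbour."""
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
    return mask.astype(bool) & ~eroded


def build_window(
    fused: np.ndarray,
    labels: np.ndarray,
    nucleus_id: int,
    margin: int | None = None,
) -> NucleusWindow:
    """Cut the nucleus window: fused values inside the rough mask, the
    boundary-mean intensity everywhere else."""
    fused = np.asarray(fused, dtype=float)
    region = labels == nucleus_id
    if not region.any():
        raise KeyError(f"nucleus id {nucleus_id} not present in label map")
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    if margin is None:
        diag = float(np.hypot(r1 - r0, c1 - c0))
        margin = max(5, int(round(0.25 * diag)))
    r0m, r1m = max(0, r0 - margin), min(fused.shape[0], r1 + margin)
    c0m, c1m = max(0, c0 - margin), min(fused.shape[1], c1 + margin)
    rough = region[r0m:r1m, c0m:c1m]
    window_fused = fused[r0m:r1m, c0m:c1m]
    boundary = _boundary_pixels(rough)
    boundary_mean = float(window_fused[boundary].mean()) if boundary.any() else 0.0
    composite = np.where(rough, window_fused, boundary_mean)
    return NucleusWindow(
        bounds=(r0m, r1m, c0m, c1m),
        composite=composite,
        rough_mask=as_binary(rough),
        boundary_mean=boundary_mean,
    )


def _two_means(points: np.ndarray, init: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic Lloyd iteration with fixed initial centers.

    Returns the cluster index per point.  Empty clusters keep their center.
    """
    centers = init.astype(float).copy()
    assign = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in range(2):
            sel = assign == k
            if sel.any():
                centers[k] = points[sel].mean(axis=0)
    return assign


def refine_boundary(window: NucleusWindow, params: RefineParams | None = None) -> np.ndarray:
    """2-means refinement of one window; returns the refined binary mask.

    Features: I = composite * w1 (w1 = 1 / window max), B = rough mask * w2.
    The cluster with higher mean B is foreground; the result is the largest
    8-connected component with holes filled.  Degenerate windows fall back
    to the rough mask.
    """
    params = params or RefineParams()
    comp = window.composite
    rough = window.rough_mask.astype(bool)
    vmax = float(comp.max())
    if vmax <= 0:
        return window.rough_mask.copy()
    w1 = 1.0 / vmax
    I = comp.ravel() * w1
    B = rough.ravel().astype(float) * params.w2
    pts = np.stack([I, B], axis=1)
    if np.allclose(pts, pts[0]):
        return window.rough_mask.copy()
    c_fg = pts[rough.ravel()].mean(axis=0)
    c_bg = pts[~rough.ravel()].mean(axis=0) if (~rough).any() else c_fg + 1e-6
    assign = _two_means(pts, np.stack([c_bg, c_fg]))
    # foreground = cluster with higher mean rough-membership weight
    mean_b = [B[assign == k].mean() if (assign == k).any() else -1.0 for k in range(2)]
    fg = (assign == int(np.argmax(mean_b))).reshape(comp.shape)
    if not fg.any():
        return window.rough_mask.copy()
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return window.rough_mask.copy()
    return as_binary(fg)


def refine_all(
    fused: np.ndarray, labels: np.ndarray, params: RefineParams | None = None
) -> np.ndarray:
    """Refine every nucleus and reassemble a label map.

    A contested pixel goes to the nucleus whose rough region owned it;
    pixels outside every rough region go to the first claimant.
    """
    params = params or RefineParams()
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        window = build_window(fused, labels, lab, params.margin)
        refined = refine_boundary(window, params)
        r0, r1, c0, c1 = window.bounds
        sub_out = out[r0:r1, c0:c1]
        sub_rough = labels[r0:r1, c0:c1]
        claim = refined.astype(bool) & ((sub_out == 0) | (sub_rough == lab)) & (
            (sub_rough == 0) | (sub_rough == lab)
        )
        sub_out[claim] = lab
    return out
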
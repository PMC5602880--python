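"""Nucleus segmentation: channel fusion, binarization, seeded cluster splitting.

Stages: fuse the two channels into a contrast-enhanced raster, binarize it
(global Otsu with a local-window fallback), compute the Euclidean distance
map, detect and merge seeds at the smoothed local maxima, split touching
nuclei by watershed on the inverted distance map, and drop small/dim
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.draw import line as draw_line
from skimage.segmentation import watershed

from .image import SeedSet, TwoChannelImage, as_binary, relabel_consecutive


@dataclass
class FusionParams:
    """Channel weights for fusion; defaults follow the green-heavier mix."""

    w_g: float = 0.6
    w_r: float = 0.4

    def __post_init__(self) -> None:
        if self.w_g < 0 or self.w_r < 0:
            raise ValueError("fusion weights must be non-negative")


@dataclass
class SegmentParams:
    """Tunable knobs of the segmentation stage."""

    fusion: FusionParams | None = None
    local_window: int = 701
    sigma: float = 2.0
    merge_ratio: float = 0.928
    min_area: int = 80
    min_mean_intensity: float | None = None  # default: 0.5 * Otsu of fused
    exact_local: bool = False

    def __post_init__(self) -> None:
        if self.fusion is None:
            self.fusion = FusionParams()


class ConstantImageError(ValueError):
    """Raised when a threshold is requested for a constant image."""


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the histogram.

    Foreground is ``image > threshold``.  Integer images with a small value
    range use one histogram bin per gray level so the result matches an
    exhaustive search over integer cut points exactly.
    """
    values = np.asarray(image).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ConstantImageError("constant image has no valid threshold")
    if np.issubdtype(values.dtype, np.integer) and (vmax - vmin) < nbins:
        edges = np.arange(np.floor(vmin) - 0.5, np.ceil(vmax) + 1.5)
        centers = np.arange(np.floor(vmin), np.ceil(vmax) + 1)
    else:
        edges = np.linspace(vmin, vmax, nbins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.histogram(values, bins=edges)[0].astype(float)

    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m0 = np.cumsum(hist * centers)
    mtot = m0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between[:-1], nan=-1.0)
    return float(centers[int(np.argmax(between))])


def otsu_effectiveness(image: np.ndarray, threshold: float) -> float:
    """Between-class variance at ``threshold`` over total variance, in [0,1]."""
    values = np.asarray(image, dtype=float).ravel()
    total = values.var()
    if total == 0:
        return 0.0
    fg = values > threshold
    w1 = fg.mean()
    w0 = 1.0 - w1
    if w0 == 0 or w1 == 0:
        return 0.0
    between = w0 * w1 * (values[~fg].mean() - values[fg].mean()) ** 2
    return float(between / total)


def fuse_channels(
    img: TwoChannelImage, params: FusionParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse green and red channels; returns ``(fused, I_b)``.

    ``I_b`` is the Otsu binarization of the green channel and gates the red
    contribution:  fused = I_g * (P*w_g/P_g) + I_r * I_b * (P*w_r/P_r).
    """
    params = params or FusionParams()
    p_g = float(img.green.max())
    if p_g <= 0:
        raise ValueError("green channel is all zero; nothing to fuse")
    try:
        i_b = as_binary(img.green > otsu_threshold(img.green))
    except ConstantImageError:
        i_b = np.ones_like(img.green, dtype=np.uint8)
    p_r = float(img.red.max())
    fused = img.green * (img.P * params.w_g / p_g)
    if p_r > 0:
        fused = fused + img.red * i_b * (img.P * params.w_r / p_r)
    return fused, i_b


def _local_threshold_grid(image: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel threshold from window-Otsu sampled on a coarse grid.

    Thresholds are computed at grid nodes with stride window//4 and
    bilinearly interpolated; windows are clipped at the image edge.
    """
    h, w = image.shape
    half = window // 2
    stride = max(window // 4, 1)
    rows = np.unique(np.clip(np.arange(0, h + stride, stride), 0, h - 1))
    cols = np.unique(np.clip(np.arange(0, w + stride, stride), 0, w - 1))
    grid = np.empty((len(rows), len(cols)))
    global_fallback = float(np.mean(image))
    for i, r in enumerate(rows):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        for j, c in enumerate(cols):
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            block = image[r0:r1, c0:c1]
            try:
                grid[i, j] = otsu_threshold(block)
            except ConstantImageError:
                # constant window: nothing exceeds its own value
                grid[i, j] = float(block.flat[0]) if block.size else global_fallback
    if len(rows) == 1 and len(cols) == 1:
        return np.full(image.shape, grid[0, 0])
    interp = RegularGridInterpolator(
        (rows.astype(float), cols.astype(float)),
        grid,
        method="linear" if min(len(rows), len(cols)) > 1 else "nearest",
        bounds_error=False,
        fill_value=None,
    )
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    return interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(h, w)


def _local_threshold_exact(image: np.ndarray, window: int) -> np.ndarray:
    h, w = image.shape
    half = window // 2
    out = np.empty_like(image, dtype=float)
    for r in range(h):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        for c in range(w):
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            block = image[r0:r1, c0:c1]
            try:
                out[r, c] = otsu_threshold(block)
            except ConstantImageError:
                out[r, c] = float(block.flat[0])
    return out


def global_otsu_failed(
    image: np.ndarray,
    threshold: float,
    fg_bounds: tuple[float, float] = (0.001, 0.40),
    min_effectiveness: float = 0.5,
) -> bool:
    """Deterministic failure check for the global threshold.

    Global Otsu is declared failed when the foreground fraction leaves
    plausible nucleus coverage or the threshold separates the histogram
    poorly (between-class / total variance below ``min_effectiveness``).
    """
    frac = float(np.mean(image > threshold))
    if not (fg_bounds[0] <= frac <= fg_bounds[1]):
        return True
    return otsu_effectiveness(image, threshold) < min_effectiveness


def binarize(
    fused: np.ndarray,
    window: int = 701,
    exact_local: bool = False,
    fg_bounds: tuple[float, float] = (0.001, 0.40),
    min_effectiveness: float = 0.5,
) -> np.ndarray:
    """Binarize the fused image: global Otsu, falling back to local windows."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    fused = np.asarray(fused, dtype=float)
    try:
        t = otsu_threshold(fused)
    except ConstantImageError:
        return np.zeros(fused.shape, dtype=np.uint8)
    if not global_otsu_failed(fused, t, fg_bounds, min_effectiveness):
        return as_binary(fused > t)
    local = (
        _local_threshold_exact(fused, window)
        if exact_local
        else _local_threshold_grid(fused, window)
    )
    # tolerance absorbs interpolation round-off on flat backgrounds
    return as_binary(fused > local + 1e-9 * (1.0 + np.abs(local)))


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of each foreground pixel to the nearest zero."""
    mask = as_binary(mask)
    if mask.min() != 0:
        raise ValueError("mask has no zero pixel; distance map undefined")
    return ndimage.distance_transform_edt(mask)


def detect_seeds(D: np.ndarray, sigma: float = 2.0) -> SeedSet:
    """Strict local maxima of the Gaussian-smoothed distance map.

    Plateaus (flat connected maxima) are collapsed to the plateau pixel
    nearest its centroid.  Returned values are read from the smoothed map.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    D = np.asarray(D, dtype=float)
    smoothed = ndimage.gaussian_filter(D, sigma) if sigma > 0 else D
    fg = D > 0
    if not fg.any():
        return SeedSet([], [])
    maxfilt = ndimage.maximum_filter(smoothed, size=3, mode="constant", cval=-np.inf)
    candidates = (smoothed >= maxfilt) & fg
    plateau_labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    locations: list[tuple[int, int]] = []
    values: list[float] = []
    for lab in range(1, n + 1):
        pix = np.argwhere(plateau_labels == lab)
        centroid = pix.mean(axis=0)
        best = pix[np.argmin(((pix - centroid) ** 2).sum(axis=1))]
        loc = (int(best[0]), int(best[1]))
        locations.append(loc)
        values.append(float(smoothed[loc]))
    order = np.argsort([-v for v in values], kind="stable")
    return SeedSet(
        [locations[i] for i in order], [values[i] for i in order]
    )


def merge_seeds(seeds: SeedSet, D: np.ndarray, r: float = 0.928) -> SeedSet:
    """Merge seed pairs whose connecting ridge stays close to the lower seed.

    For a pair with lower value ``m`` and line minimum ``n``: if ``n > m*r``
    the pair collapses to its midpoint (value re-read from ``D``).  Pairs
    are tried nearest-first and the process iterates to a fixpoint.
    """
    if not (0 < r <= 1):
        raise ValueError("merge ratio r must be in (0, 1]")
    D = np.asarray(D, dtype=float)
    locs = list(seeds.locations)
    vals = list(seeds.values)
    merged = True
    while merged and len(locs) > 1:
        merged = False
        pairs = sorted(
            (
                ((locs[i][0] - locs[j][0]) ** 2 + (locs[i][1] - locs[j][1]) ** 2, i, j)
                for i in range(len(locs))
                for j in range(i + 1, len(locs))
            ),
        )
        for _, i, j in pairs:
            m = min(vals[i], vals[j])
            rr, cc = draw_line(locs[i][0], locs[i][1], locs[j][0], locs[j][1])
            n = float(D[rr, cc].min())
            if n > m * r:
                # midpoint snapped onto the rasterized line so it stays on
                # foreground (every line pixel has D >= n > 0)
                k = len(rr) // 2
                mid = (int(rr[k]), int(cc[k]))
                for k in sorted((i, j), reverse=True):
                    del locs[k], vals[k]
                if mid not in locs:
                    locs.append(mid)
                    vals.append(float(D[mid]))
                merged = True
                break
    return SeedSet(locs, vals)


def split_clusters(mask: np.ndarray, seeds: SeedSet, D: np.ndarray) -> np.ndarray:
    """Watershed of the inverted distance map with seeds forced as minima."""
    mask = as_binary(mask)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (loc, _) in enumerate(seeds, start=1):
        if not mask[loc]:
            raise ValueError(f"seed {loc} lies on background")
        markers[loc] = k
    if len(seeds) == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    labels = watershed(-np.asarray(D, dtype=float), markers=markers, mask=mask.astype(bool), connectivity=2)
    return labels.astype(np.int32)


def filter_regions(
    labels: np.ndarray,
    fused: np.ndarray,
    min_area: float = 80,
    min_mean_intensity: float | None = None,
) -> np.ndarray:
    """Drop regions that are too small or too dark, then renumber labels."""
    if min_area < 0 or (min_mean_intensity is not None and min_mean_intensity < 0):
        raise ValueError("thresholds must be >= 0")
    labels = np.asarray(labels)
    fused = np.asarray(fused, dtype=float)
    if min_mean_intensity is None:
        try:
            min_mean_intensity = 0.5 * otsu_threshold(fused)
        except ConstantImageError:
            min_mean_intensity = 0.0
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        region = labels == lab
        if region.sum() < min_area or fused[region].mean() < min_mean_intensity:
            out[region] = 0
    return relabel_consecutive(out)


def segment_image(
    img: TwoChannelImage, params: SegmentParams | None = None
) -> dict[str, np.ndarray]:
    """Run the full rough-segmentation chain; returns every intermediate."""
    params = params or SegmentParams()
    fused, i_b = fuse_channels(img, params.fusion)
    mask = binarize(fused, window=params.local_window, exact_local=params.exact_local)
    if not mask.any():
        empty = np.zeros(mask.shape, dtype=np.int32)
        return {"fused": fused, "green_mask": i_b, "mask": mask, "distance": mask.astype(float), "labels": empty}
    # guarantee a zero border for the distance transform
    if mask.min() != 0:
        warnings.warn("binary mask covers the whole frame; treating border as zero")
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = 0
    D = distance_map(mask)
    smoothed = ndimage.gaussian_filter(D, params.sigma) if params.sigma > 0 else D
    seeds = detect_seeds(D, params.sigma)
    seeds = merge_seeds(seeds, smoothed, params.merge_ratio)
    labels = split_clusters(mask, seeds, D)
    labels = filter_regions(labels, fused, params.min_area, params.min_mean_intensity)
    return {
        "fused": fused,
        "green_mask": i_b,
        "mask": mask,
        "distance": D,
        "labels": labels,
    }
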
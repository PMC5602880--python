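"""Per-nucleus feature battery: geometry, intensity moments, masked GLCM.

The canonical table has 49 feature columns: 9 geometric, 4 intensity
moments per channel, and 4 co-occurrence statistics x 4 directions per
channel.  Statistics follow the printed formulas exactly (sample moments
use a 1/(N-1) denominator; perimeter is the contour pixel count, so
circularity of small digital disks may slightly exceed 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

from .image import TwoChannelImage, as_binary

GLCM_DIRECTIONS = (0, 45, 90, 135)
#: row/col pixel offsets per direction for unit distance
_DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

CHANNELS = ("green", "red")

GEOMETRIC_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "ellipticity",
    "solidity",
    "curvature_max",
    "curvature_min",
    "curvature_std",
    "curvature_mean",
)
INTENSITY_NAMES = ("mean", "variance", "skewness", "kurtosis")
GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")


def feature_columns() -> list[str]:
    """The frozen 49-column feature layout."""
    cols = list(GEOMETRIC_NAMES)
    for ch in CHANNELS:
        cols += [f"{ch}_{name}" for name in INTENSITY_NAMES]
    for ch in CHANNELS:
        for name in GLCM_NAMES:
            cols += [f"{ch}_glcm_{name}_{d}" for d in GLCM_DIRECTIONS]
    return cols


@dataclass
class GLCMSpec:
    offset: int = 7
    levels: int = 32
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass
class NucleusRegion:
    """One segmented nucleus with its traced boundary and pixel values."""

    nucleus_id: int
    mask: np.ndarray
    boundary: list[tuple[int, int]]
    green_pixels: np.ndarray
    red_pixels: np.ndarray
    green_patch: np.ndarray = field(default=None, repr=False)
    red_patch: np.ndarray = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# region extraction


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbour boundary trace, one closed 8-connected loop.

    Starts at the topmost-leftmost foreground pixel and walks the outer
    contour counter-clockwise (in image coordinates with row increasing
    downward).  Single-pixel regions return a one-point loop.
    """
    mask = np.asarray(mask, dtype=bool)
    pix = np.argwhere(mask)
    if len(pix) == 0:
        raise ValueError("empty mask")
    start = tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))[0]])
    if len(pix) == 1:
        return [start]

    def neighbors(p):
        for dr, dc in _MOORE:
            yield (p[0] + dr, p[1] + dc)

    def inside(p):
        return 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]

    contour = [start]
    # backtrack starts pointing at the pixel above the start (background,
    # since start is topmost in its column neighbourhood)
    prev = (start[0] - 1, start[1])
    cur = start
    first_next = None
    while True:
        base = _MOORE.index((prev[0] - cur[0], prev[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            cand = (
                cur[0] + _MOORE[(base + k) % 8][0],
                cur[1] + _MOORE[(base + k) % 8][1],
            )
            if inside(cand):
                nxt = cand
                prev = (
                    cur[0] + _MOORE[(base + k - 1) % 8][0],
                    cur[1] + _MOORE[(base + k - 1) % 8][1],
                )
                break
        if nxt is None:  # isolated pixel (should be caught above)
            break
        if first_next is None:
            first_next = nxt
        elif cur == start and nxt == first_next:
            break  # Jacob's stopping criterion: same entry repeated
        contour.append(nxt)
        cur = nxt
        if len(contour) > 4 * mask.size:
            raise RuntimeError("boundary trace failed to close")
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return contour


def extract_region(
    labels: np.ndarray, img: TwoChannelImage, nucleus_id: int
) -> NucleusRegion:
    """Cut one nucleus out of the label map with its traced contour."""
    region = np.asarray(labels) == nucleus_id
    if not region.any():
        raise KeyError(f"nucleus id {nucleus_id} not in label map")
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    mask = region[sl]
    boundary = trace_boundary(mask)
    return NucleusRegion(
        nucleus_id=int(nucleus_id),
        mask=as_binary(mask),
        boundary=boundary,
        green_pixels=img.green[sl][mask],
        red_pixels=img.red[sl][mask],
        green_patch=np.where(mask, img.green[sl], np.nan),
        red_patch=np.where(mask, img.red[sl], np.nan),
    )


# ---------------------------------------------------------------------------
# geometric features


def _min_area_rectangle(mask: np.ndarray) -> tuple[float, float]:
    """Side lengths (a >= b) of the minimum-area enclosing rectangle.

    Pixels are treated as unit squares (hull over the four corners of each
    boundary pixel), so an axis-aligned w x h rectangle of pixels measures
    exactly w x h.  Rotating calipers over hull edge orientations.
    """
    boundary = np.argwhere(mask & ~ndimage.binary_erosion(mask))
    if len(boundary) == 0:
        boundary = np.argwhere(mask)
    corners = np.concatenate(
        [boundary + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    try:
        hull = ConvexHull(corners)
        pts = corners[hull.vertices]
    except QhullError:
        pts = corners
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 0], edges[:, 1]), np.pi / 2))
    best = None
    for ang in angles:
        c, s = np.cos(ang), np.sin(ang)
        rot = pts @ np.array([[c, -s], [s, c]])
        span = rot.max(axis=0) - rot.min(axis=0)
        area = span[0] * span[1]
        if best is None or area < best[0]:
            best = (area, max(span), min(span))
    return float(best[1]), float(best[2])


def _curvatures(boundary: list[tuple[int, int]], spacing: int = 10) -> np.ndarray:
    """Signed curvature at each boundary point from the circle through the
    points ``spacing`` steps away on either side (cyclic)."""
    pts = np.asarray(boundary, dtype=float)
    n = len(pts)
    s = min(spacing, max(1, n // 2 - 1)) if n < 2 * spacing + 1 else spacing
    p1 = pts[(np.arange(n) - s) % n]
    p2 = pts
    p3 = pts[(np.arange(n) + s) % n]
    a = p2 - p1
    b = p3 - p1
    c = p3 - p2
    # negated so convex (outward-bulging) boundary points get positive kappa
    cross = -(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    la = np.hypot(a[:, 0], a[:, 1])
    lb = np.hypot(b[:, 0], b[:, 1])
    lc = np.hypot(c[:, 0], c[:, 1])
    denom = la * lb * lc
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return kappa


def contour_length(boundary: list[tuple[int, int]]) -> float:
    """Closed-loop length of the traced contour (axial 1, diagonal sqrt 2).

    Equals the contour pixel count on axis-aligned shapes; on curved
    shapes it tracks the true arc length, keeping circularity of digital
    disks near 1.
    """
    if len(boundary) < 2:
        return float(len(boundary))
    pts = np.asarray(boundary + [boundary[0]], dtype=float)
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def geometric_features(region: NucleusRegion) -> dict[str, float]:
    """Nine shape descriptors of the region mask and contour."""
    mask = region.mask.astype(bool)
    if not mask.any():
        raise ValueError("empty region")
    filled = ndimage.binary_fill_holes(mask)
    A = float(filled.sum())
    P = contour_length(region.boundary)
    C = 4.0 * np.pi * A / P**2 if P > 0 else np.nan
    a, b = _min_area_rectangle(filled)
    ellipticity = 1.0 - (b / a if a > 0 else 1.0)
    hull_area = float(convex_hull_image(filled).sum()) if A > 2 else A
    solidity = A / hull_area if hull_area > 0 else 1.0
    kappa = _curvatures(region.boundary)
    return {
        "area": A,
        "perimeter": P,
        "circularity": C,
        "ellipticity": ellipticity,
        "solidity": solidity,
        "curvature_max": float(kappa.max()),
        "curvature_min": float(kappa.min()),
        "curvature_std": float(kappa.std()),
        "curvature_mean": float(np.abs(kappa).mean()),
    }


# ---------------------------------------------------------------------------
# intensity features


def intensity_features(values: np.ndarray) -> tuple[dict[str, float], bool]:
    """Mean, sample variance, and the printed 1/(N-1) skewness/kurtosis.

    Returns (features, degenerate_flag); zero spread stores 0 for the
    standardized moments and flags the row.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pixels for intensity moments")
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    degenerate = var == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        sigma = np.sqrt(var)
        z = (x - mean) / sigma
        skew = float((z**3).sum() / (n - 1))
        kurt = float((z**4).sum() / (n - 1))
    return (
        {"mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt},
        degenerate,
    )


# ---------------------------------------------------------------------------
# texture features


def _quantize(patch: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of in-mask values to 0..levels-1."""
    finite = patch[np.isfinite(patch)]
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        return np.where(np.isfinite(patch), 0, -1).astype(int)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(float)
    q = np.clip(q, 0, levels - 1)
    return np.where(np.isfinite(patch), q, -1).astype(int)


def glcm(
    patch: np.ndarray, spec: GLCMSpec, direction: int
) -> np.ndarray:
    """Masked co-occurrence matrix of a NaN-padded intensity patch.

    Only pairs with both pixels inside the mask (non-NaN) are counted.
    Raises ``ValueError`` when the region admits no valid pair at the
    requested offset.
    """
    if direction not in _DIRECTION_STEPS:
        raise ValueError(f"direction must be one of {GLCM_DIRECTIONS}")
    q = _quantize(np.asarray(patch, dtype=float), spec.levels)
    dr, dc = (d * spec.offset for d in _DIRECTION_STEPS[direction])
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("region thinner than GLCM offset; no valid pairs")
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (src >= 0) & (dst >= 0)
    if not valid.any():
        raise ValueError("region thinner than GLCM offset; no valid pairs")
    C = np.zeros((spec.levels, spec.levels), dtype=float)
    np.add.at(C, (src[valid], dst[valid]), 1.0)
    if spec.symmetric:
        C = C + C.T
    if spec.normalized:
        C = C / C.sum()
    return C


def glcm_features(C: np.ndarray) -> tuple[dict[str, float], bool]:
    """Contrast, correlation, energy, homogeneity of a normalized GLCM.

    Returns (features, correlation_undefined_flag).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float((np.abs(i - j) ** 2 * C).sum())
    energy = float((C**2).sum())
    homogeneity = float((C / (1.0 + np.abs(i - j))).sum())
    p_i = C.sum(axis=1)
    p_j = C.sum(axis=0)
    mu_i = float((np.arange(n) * p_i).sum())
    mu_j = float((np.arange(n) * p_j).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * p_i).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * p_j).sum())
    undefined = var_i == 0.0 or var_j == 0.0
    if undefined:
        correlation = 0.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * C).sum()) / np.sqrt(var_i * var_j)
        )
    return (
        {
            "contrast": contrast,
            "correlation": correlation,
            "energy": energy,
            "homogeneity": homogeneity,
        },
        undefined,
    )


# ---------------------------------------------------------------------------
# table assembly


def feature_table(
    labels: np.ndarray,
    img: TwoChannelImage,
    spec: GLCMSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row of the canonical 49-column layout per nucleus.

    Returns ``(table, flags)``; ``flags`` marks entries whose value is a
    defined placeholder (degenerate moments, undefined correlation, regions
    thinner than the co-occurrence offset).
    """
    spec = spec or GLCMSpec()
    cols = feature_columns()
    rows, flag_rows, ids = [], [], []
    for lab in (int(v) for v in np.unique(labels) if v != 0):
        region = extract_region(labels, img, lab)
        row: dict[str, float] = {}
        flags: dict[str, bool] = {c: False for c in cols}
        row.update(geometric_features(region))
        if len(region.boundary) < 21:
            for name in GEOMETRIC_NAMES[5:]:
                flags[name] = True
        for ch in CHANNELS:
            values = region.green_pixels if ch == "green" else region.red_pixels
            feats, degenerate = intensity_features(values)
            for k, v in feats.items():
                row[f"{ch}_{k}"] = v
            if degenerate:
                flags[f"{ch}_skewness"] = flags[f"{ch}_kurtosis"] = True
            patch = region.green_patch if ch == "green" else region.red_patch
            for d in GLCM_DIRECTIONS:
                try:
                    feats, undef = glcm_features(glcm(patch, spec, d))
                except ValueError:
                    feats = {k: 0.0 for k in GLCM_NAMES}
                    undef = True
                    for name in GLCM_NAMES:
                        flags[f"{ch}_glcm_{name}_{d}"] = True
                for k, v in feats.items():
                    row[f"{ch}_glcm_{k}_{d}"] = v
                if undef:
                    flags[f"{ch}_glcm_correlation_{d}"] = True
        rows.append([row[c] for c in cols])
        flag_rows.append([flags[c] for c in cols])
        ids.append(lab)
    table = pd.DataFrame(rows, columns=cols, index=pd.Index(ids, name="nucleus_id"))
    flag_df = pd.DataFrame(
        flag_rows, columns=cols, index=pd.Index(ids, name="nucleus_id"), dtype=bool
    )
    if flag_df.to_numpy().any():
        warnings.warn("feature table contains flagged (placeholder) entries")
    return table, flag_df
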
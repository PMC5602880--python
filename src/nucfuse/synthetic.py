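"""Synthetic two-channel nucleus scenes with exact ground truth.

Renders worm-like scenes of four nucleus types (hypodermal, intestinal,
muscle, neuronal) as rim-bright ellipses in the green channel and textured
filled ellipses in the red channel, with optional touching clumps,
out-of-focus green distractors and channel-specific Gaussian noise.  The
renderer is fully deterministic given the nucleus specs and a seed, which
makes age degradation a re-render with modified specs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .image import TwoChannelImage

TISSUE_CLASSES = ("hypodermal", "intestinal", "muscle", "neuronal")

#: default class mix, hypodermal : intestinal : muscle : neuronal
DEFAULT_CLASS_MIX = (8 / 15, 2 / 15, 2 / 15, 3 / 15)

VALID_DAYS = (1, 4, 6, 10, 12, 14, 16)

# semi-major axis range and aspect-ratio (b/a) range per tissue, px on a
# 1000 x 1000 canvas
_TYPE_GEOMETRY = {
    "hypodermal": ((25.0, 40.0), (0.55, 0.85)),
    "intestinal": ((35.0, 55.0), (0.65, 0.95)),
    "muscle": ((10.0, 18.0), (0.40, 0.60)),
    "neuronal": ((8.0, 14.0), (0.85, 1.00)),
}

_TYPE_TEXTURE_AMPLITUDE = {
    "hypodermal": 0.35,
    "intestinal": 0.12,
    "muscle": 0.40,
    "neuronal": 0.40,
}

# relative interior brightness of the green channel (rim is 1.0)
_GREEN_INTERIOR = 0.40
_PSF_SIGMA = 1.0


class PlacementError(RuntimeError):
    """Canvas too crowded to place the requested nuclei."""


@dataclass
class NucleusSpec:
    """Geometry and photometry of one synthetic nucleus."""

    tissue_class: str
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b
    rotation: float  # radians
    age_day: int = 1
    boundary_perturbation: float = 0.02
    texture_scale: float = 7.0
    peak_intensity_green: float = 8000.0
    peak_intensity_red: float = 8000.0
    texture_amplitude: float = 0.45  # chromatin texture depth, 0 = smooth
    wobble_seed: int = 0  # per-nucleus stream for boundary/texture noise

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.peak_intensity_green <= 0 or self.peak_intensity_red <= 0:
            raise ValueError("peak intensities must be positive")


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene."""

    label_map: np.ndarray
    classes: dict[int, str]
    specs: list[NucleusSpec]
    rng_seed: int
    noise_level: float = 0.0
    n_distractors: int = 0

    def __post_init__(self) -> None:
        present = {int(v) for v in np.unique(self.label_map) if v != 0}
        missing = present - set(self.classes)
        if missing:
            raise ValueError(f"labels without class entry: {sorted(missing)}")


def perturbation_for_day(day: int, base: float = 0.02) -> float:
    """Boundary perturbation amplitude, non-decreasing in age."""
    return base + 0.013 * (day - 1)


def noise_scale_for_day(day: int) -> float:
    """Background-noise multiplier, non-decreasing in age."""
    return 1.0 + 0.05 * (day - 1)


def _boundary_profile(theta: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order Fourier wobble of the nominal ellipse boundary."""
    out = np.zeros_like(theta)
    for k in range(2, 6):
        out += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
    return 1.0 + amplitude * out / 2.0


def _render_nucleus(
    spec: NucleusSpec, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    """Rasterize one nucleus; returns (mask, green, red, bbox offset)."""
    a, b = spec.semi_axes
    rng = np.random.default_rng(spec.wobble_seed)
    pad = int(np.ceil(max(a, b) * (1.0 + 3.0 * spec.boundary_perturbation))) + 4
    r0 = max(0, int(spec.center[0]) - pad)
    r1 = min(shape[0], int(spec.center[0]) + pad + 1)
    c0 = max(0, int(spec.center[1]) - pad)
    c1 = min(shape[1], int(spec.center[1]) + pad + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    ct, st = np.cos(spec.rotation), np.sin(spec.rotation)
    x = (dc * ct + dr * st) / a
    y = (-dc * st + dr * ct) / b
    u = np.hypot(x, y)  # normalized elliptical radius
    theta = np.arctan2(y, x)
    wobble = _boundary_profile(theta, spec.boundary_perturbation, rng)
    mask = u <= wobble

    # green: bright lamina rim just inside the boundary, dimmer interior;
    # the rim peak sits at u = wobble - rim_width so its outer tail decays
    # across the true boundary instead of beyond it
    rim_width = 0.10
    rim_center = wobble - rim_width
    rim = np.exp(-(((u - rim_center) / rim_width) ** 2))
    green = np.where(mask, np.maximum(rim, _GREEN_INTERIOR), rim * (u < wobble + rim_width))
    green = green * spec.peak_intensity_green

    # red: filled chromatin with band-limited texture near texture_scale px
    texture = rng.normal(size=mask.shape)
    texture = ndimage.gaussian_filter(texture, spec.texture_scale / 2.355)
    span = texture.max() - texture.min()
    if span > 0:
        texture = (texture - texture.min()) / span
    amp = spec.texture_amplitude
    red = np.where(mask, (1.0 - amp + amp * texture) * spec.peak_intensity_red, 0.0)
    return mask, green, red, (r0, c0)


def _sample_spec(
    tissue: str,
    center: tuple[float, float],
    age_day: int,
    peak: float,
    rng: np.random.Generator,
    scale: float = 1.0,
) -> NucleusSpec:
    (a_lo, a_hi), (ba_lo, ba_hi) = _TYPE_GEOMETRY[tissue]
    a = rng.uniform(a_lo, a_hi) * scale
    b = a * rng.uniform(ba_lo, ba_hi)
    # intestinal chromatin is homogeneous; hypodermal roughens with age
    amplitude = _TYPE_TEXTURE_AMPLITUDE[tissue]
    if tissue == "hypodermal":
        amplitude = min(0.6, amplitude + 0.015 * (age_day - 1))
    return NucleusSpec(
        tissue_class=tissue,
        center=center,
        semi_axes=(a, b),
        rotation=rng.uniform(0, np.pi),
        age_day=age_day,
        boundary_perturbation=perturbation_for_day(age_day),
        texture_scale=7.0,
        texture_amplitude=amplitude,
        peak_intensity_green=peak * rng.uniform(0.85, 1.0),
        peak_intensity_red=peak * rng.uniform(0.75, 1.0),
        wobble_seed=int(rng.integers(0, 2**31 - 1)),
    )


def render_scene(
    specs: list[NucleusSpec],
    shape: tuple[int, int],
    noise_level: float,
    seed: int,
    P: float = 10000.0,
    distractors: int = 0,
) -> tuple[TwoChannelImage, SceneTruth]:
    """Deterministically rasterize ``specs`` into a two-channel image."""
    rng = np.random.default_rng(seed)
    green = np.zeros(shape, dtype=float)
    red = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    classes: dict[int, str] = {}
    for k, spec in enumerate(specs, start=1):
        mask, g, r, (r0, c0) = _render_nucleus(spec, shape)
        sl = (slice(r0, r0 + mask.shape[0]), slice(c0, c0 + mask.shape[1]))
        green[sl] = np.maximum(green[sl], g)
        red[sl] = np.maximum(red[sl], r)
        # earlier nuclei keep contested pixels so truth stays a partition
        region = mask & (labels[sl] == 0)
        labels[sl][region] = k
        classes[k] = spec.tissue_class

    # out-of-focus distractors: dim, heavily blurred, green only
    for _ in range(distractors):
        blob = np.zeros(shape)
        rc = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        rad = rng.uniform(10, 25)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        blob[(rr - rc[0]) ** 2 + (cc - rc[1]) ** 2 <= rad**2] = 1.0
        blob = ndimage.gaussian_filter(blob, 8.0)
        green += blob * 0.06 * P

    green = ndimage.gaussian_filter(green, _PSF_SIGMA)
    red = ndimage.gaussian_filter(red, _PSF_SIGMA)
    if noise_level > 0:
        green = green + rng.normal(0.0, noise_level, shape)
        red = red + rng.normal(0.0, 2.0 * noise_level, shape)
    green = np.clip(green, 0, P)
    red = np.clip(red, 0, P)
    img = TwoChannelImage(green=green, red=red, P=P)
    truth = SceneTruth(
        label_map=labels,
        classes=classes,
        specs=list(specs),
        rng_seed=seed,
        noise_level=noise_level,
        n_distractors=distractors,
    )
    return img, truth


def _place_centers(
    tissues: list[str],
    shape: tuple[int, int],
    clump_fraction: float,
    rng: np.random.Generator,
    max_retries: int = 200,
    scale: float = 1.0,
) -> list[tuple[float, float]]:
    """Rejection-sample centers; clumped nuclei touch a prior neighbour and
    neuronal nuclei gravitate to a shared cluster anchor."""
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    margin = 12.0
    anchor = (rng.uniform(0.25, 0.75) * shape[0], rng.uniform(0.25, 0.75) * shape[1])
    n_clump = int(round(clump_fraction * len(tissues)))
    for idx, tissue in enumerate(tissues):
        (a_lo, a_hi), _ = _TYPE_GEOMETRY[tissue]
        rad = 0.5 * (a_lo + a_hi) * scale
        placed = False
        for _ in range(max_retries):
            if idx > 0 and idx <= n_clump:
                j = int(rng.integers(0, len(centers)))
                ang = rng.uniform(0, 2 * np.pi)
                d = (radii[j] + rad) * 0.95
                cand = (centers[j][0] + d * np.sin(ang), centers[j][1] + d * np.cos(ang))
            elif tissue == "neuronal":
                cand = (
                    anchor[0] + rng.normal(0, 0.08 * shape[0]),
                    anchor[1] + rng.normal(0, 0.08 * shape[1]),
                )
            else:
                lo0, hi0 = margin + rad, shape[0] - margin - rad
                lo1, hi1 = margin + rad, shape[1] - margin - rad
                if lo0 >= hi0 or lo1 >= hi1:
                    raise PlacementError(
                        f"canvas {shape} too small for a nucleus of radius {rad:.0f}"
                    )
                cand = (rng.uniform(lo0, hi0), rng.uniform(lo1, hi1))
            if not (
                margin <= cand[0] < shape[0] - margin
                and margin <= cand[1] < shape[1] - margin
            ):
                continue
            too_close = any(
                np.hypot(cand[0] - c[0], cand[1] - c[1]) < 0.8 * (rad + rr)
                for c, rr in zip(centers, radii)
            )
            if not too_close:
                centers.append(cand)
                radii.append(rad)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {idx + 1}/{len(tissues)} on canvas {shape}"
            )
    return centers


def generate_scene(
    n_nuclei: int,
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX,
    age_day: int = 1,
    clump_fraction: float = 0.0,
    noise_level: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (1000, 1000),
    P: float = 10000.0,
    n_distractors: int = 2,
) -> tuple[TwoChannelImage, SceneTruth]:
    """Generate a random scene with ``n_nuclei`` nuclei and exact truth."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be non-negative proportions summing to 1")
    if not 0 <= clump_fraction <= 1:
        raise ValueError("clump_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tissues = [TISSUE_CLASSES[i] for i in rng.choice(4, size=n_nuclei, p=mix)]
    # put clumped nuclei first so the clump chain references prior centers
    scale = float(np.clip(min(shape) / 700.0, 0.5, 1.0))
    centers = _place_centers(tissues, shape, clump_fraction, rng, scale=scale)
    specs = [
        _sample_spec(t, c, age_day, 0.9 * P, rng, scale=scale)
        for t, c in zip(tissues, centers)
    ]
    noise = noise_level * noise_scale_for_day(age_day)
    return render_scene(
        specs,
        shape,
        noise,
        seed=seed + 1,
        P=P,
        distractors=n_distractors,
    )


def degrade_with_age(
    img: TwoChannelImage, truth: SceneTruth, from_day: int, to_day: int
) -> tuple[TwoChannelImage, SceneTruth]:
    """Re-render the scene as it would look ``to_day`` days into adulthood.

    Boundary perturbation and background noise grow with age; the truth
    label map is re-rasterized from the perturbed specs.
    """
    if to_day < from_day:
        raise ValueError("to_day must be >= from_day")
    specs = []
    for spec in truth.specs:
        d = asdict(spec)
        d["age_day"] = to_day
        d["boundary_perturbation"] = perturbation_for_day(
            to_day, base=spec.boundary_perturbation - 0.013 * (from_day - 1)
        )
        d["center"] = tuple(d["center"])
        d["semi_axes"] = tuple(d["semi_axes"])
        specs.append(NucleusSpec(**d))
    noise = truth.noise_level * (
        noise_scale_for_day(to_day) / noise_scale_for_day(from_day)
    )
    return render_scene(
        specs,
        img.shape,
        noise,
        seed=truth.rng_seed,
        P=img.P,
        distractors=truth.n_distractors,
    )


def planted_feature_table(
    seed: int,
    n_samples: int = 2000,
    n_features: int = 49,
    detector_noise: float = 0.15,
    spread_noise: float = 0.5,
):
    """Feature-space benchmark with exactly 5 informative columns.

    Four classes; column 0 detects class A, column 1 detects class B, and
    columns 2-4 are three independent noisy reads of a class-C detector, so
    the C/D pair only separates well once all three are pooled.  The
    remaining columns are pure noise.  Returns ``(DataFrame, labels)``;
    informative columns are ``f0..f4``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, n_samples)
    X = rng.normal(0.0, 1.0, (n_samples, n_features))
    X[:, 0] = (y == 0) + rng.normal(0, detector_noise, n_samples)
    X[:, 1] = (y == 1) + rng.normal(0, detector_noise, n_samples)
    for k in (2, 3, 4):
        X[:, k] = (y == 2) + rng.normal(0, spread_noise, n_samples)
    labels = np.array(["hypodermal", "intestinal", "muscle", "neuronal"])[y]
    return (
        pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]),
        labels,
    )


def specs_to_json(truth: SceneTruth) -> str:
    """Serialize scene specs (without rasters) as JSON."""
    payload = {
        "rng_seed": truth.rng_seed,
        "noise_level": truth.noise_level,
        "classes": {str(k): v for k, v in truth.classes.items()},
        "specs": [asdict(s) for s in truth.specs],
    }
    return json.dumps(payload, indent=2)
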
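"""End-to-end orchestration: fuse -> binarize -> seeds -> split -> filter ->
refine -> features, with every intermediate kept for inspection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import GLCMSpec, feature_table
from .image import TwoChannelImage
from .refine import RefineParams, refine_all
from .segment import FusionParams, SegmentParams, segment_image

log = logging.getLogger("nucfuse")


@dataclass
class PipelineResult:
    fused: np.ndarray
    mask: np.ndarray
    distance: np.ndarray
    rough_labels: np.ndarray
    labels: np.ndarray
    features: pd.DataFrame
    flags: pd.DataFrame
    params: dict = field(default_factory=dict)


def run_pipeline(
    img: TwoChannelImage,
    config: dict | None = None,
    compute_features: bool = True,
) -> PipelineResult:
    """Run segmentation + refinement (+ features) on one image pair."""
    cfg = config or {}
    seg_params = SegmentParams(
        fusion=FusionParams(cfg.get("w_g", 0.6), cfg.get("w_r", 0.4)),
        local_window=cfg.get("local_window", 701),
        sigma=cfg.get("sigma", 2.0),
        merge_ratio=cfg.get("r", 0.928),
        min_area=cfg.get("min_area", 80),
        min_mean_intensity=cfg.get("min_mean_intensity"),
    )
    log.info("segmenting: %s", seg_params)
    stages = segment_image(img, seg_params)
    rough = stages["labels"]
    log.info("rough labels: %d", int(rough.max()))
    refined = refine_all(stages["fused"], rough, RefineParams(w2=cfg.get("w2", 0.4)))
    if compute_features and refined.max() > 0:
        table, flags = feature_table(
            refined,
            img,
            GLCMSpec(offset=cfg.get("glcm_offset", 7), levels=cfg.get("glcm_levels", 32)),
        )
    else:
        from .features import feature_columns

        cols = feature_columns()
        table = pd.DataFrame(columns=cols, index=pd.Index([], name="nucleus_id"))
        flags = table.astype(bool)
    return PipelineResult(
        fused=stages["fused"],
        mask=stages["mask"],
        distance=stages["distance"],
        rough_labels=rough,
        labels=refined,
        features=table,
        flags=flags,
        params=dict(cfg),
    )


def run_pipeline_green_only(
    img: TwoChannelImage, config: dict | None = None, compute_features: bool = False
) -> PipelineResult:
    """Single-channel baseline: the red channel is zeroed before fusion."""
    mono = TwoChannelImage(green=img.green, red=np.zeros_like(img.red), P=img.P)
    return run_pipeline(mono, config, compute_features)
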
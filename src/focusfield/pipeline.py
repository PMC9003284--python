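"""End-to-end segmentation: preprocess -> sharpness -> blur mask ->
pulse-coupled network -> binarize/clean, plus evaluation against ground
truth. The whole chain is deterministic for a fixed input + config."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import imgprep, ltp, metrics, pcnn
from .errors import FocusFieldError, PipelineStageError

__all__ = ["PipelineConfig", "SegmentationResult", "segment", "evaluate"]


@dataclass
class PipelineConfig:
    descriptor: ltp.DescriptorConfig = field(default_factory=ltp.DescriptorConfig)
    median_window: int = 3
    #: sharpness threshold: "adaptive" (2x map mean) or a fixed float
    ltp_threshold: object = "adaptive"
    #: edge-map threshold: "adaptive" or a fixed float
    edge_threshold: object = "adaptive"
    #: overrides forwarded to parameter estimation (e.g. f_e, max_iters)
    pcnn_overrides: dict = field(default_factory=dict)
    cleanup_min_size: int = 64
    cleanup_closing_iters: int = 2


@dataclass
class SegmentationResult:
    mask: np.ndarray  # final foreground mask, sharp = True
    sharpness: np.ndarray
    blur_masked: ltp.BlurMaskedImage
    edge: pcnn.EdgeMap
    firing: np.ndarray  # per-pixel firing iteration
    provenance: dict


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except FocusFieldError as exc:
            raise PipelineStageError(name, exc) from exc

    return wrap


def segment(img: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full stage sequence once and return all intermediates."""
    if cfg is None:
        cfg = PipelineConfig()
    gamma = _stage("preprocess")(imgprep.preprocess, img, cfg.median_window)
    sharp = _stage("sharpness")(ltp.sharpness_map, gamma, cfg.descriptor)
    if cfg.ltp_threshold == "adaptive":
        td_ltp = metrics.adaptive_threshold(sharp)
        # the 2x-mean rule presumes a near-zero blurred background mode;
        # when it exceeds the map maximum no blur population exists, so
        # the whole frame counts as sharp
        if td_ltp > float(sharp.max()):
            td_ltp = 0.0
    else:
        td_ltp = float(cfg.ltp_threshold)
    masked = _stage("blur_mask")(ltp.blur_mask, gamma, sharp, td_ltp)
    params = _stage("parameters")(
        pcnn.estimate_params, gamma, None, **cfg.pcnn_overrides
    )
    edge, state = _stage("pcnn")(pcnn.pcnn_run, masked, params)
    td_edge = None if cfg.edge_threshold == "adaptive" else float(cfg.edge_threshold)
    mask = _stage("binarize")(
        pcnn.binarize_and_clean,
        edge,
        td_edge,
        min_size=cfg.cleanup_min_size,
        closing_iters=cfg.cleanup_closing_iters,
    )
    provenance = {
        "median_window": cfg.median_window,
        "descriptor": {
            "neighbors": cfg.descriptor.neighbors,
            "radius": cfg.descriptor.radius,
            "threshold": cfg.descriptor.threshold,
            "window": cfg.descriptor.window,
            "sharp_bins": sorted(cfg.descriptor.sharp_bins),
        },
        "ltp_threshold": td_ltp,
        "edge_threshold": "adaptive" if td_edge is None else td_edge,
        "pcnn": params.to_dict(),
        "iterations": int(state.n),
    }
    return SegmentationResult(mask, sharp, masked, edge, state.fired.copy(), provenance)


def evaluate(result, gt: np.ndarray, kappa_sq: float = 0.3) -> dict:
    """Metric suite for both polarity conventions.

    ``sharp_positive`` scores the in-focus (white) class as positive;
    ``blur_positive`` scores the blurred class, matching conventions
    that define the positive region as the blurry one.
    """
    mask = result.mask if isinstance(result, SegmentationResult) else np.asarray(result)
    return {
        "sharp_positive": metrics.MetricsReport.from_masks(
            mask, gt, positive=1, kappa_sq=kappa_sq
        ).to_dict(),
        "blur_positive": metrics.MetricsReport.from_masks(
            mask, gt, positive=0, kappa_sq=kappa_sq
        ).to_dict(),
    }
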
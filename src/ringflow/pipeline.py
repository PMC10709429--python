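"""End-to-end convenience wrappers over the analysis modules."""

from __future__ import annotations

import numpy as np

from . import geometry
from .scene import SceneConfig, SceneTruth, build_scene, render_ring_stack


def analyze_ring_stack(stack: np.ndarray, *, pixel_size: float,
                       frame_interval: float, **segment_kwargs):
    """Segment an en-face ring stack and summarise its closure.

    Returns ``(RingSeries, ClosureSummary, masks)``.
    """
    masks, series = geometry.segment_stack(stack, pixel_size, frame_interval,
                                           **segment_kwargs)
    geometry.compute_metrics(series)
    summary = geometry.summarize_closure(series)
    return series, summary, masks


def recover_closure_summary(config: SceneConfig):
    """Render a scene and recover its closure summary from the images.

    Returns ``(measured_summary, truth_summary, truth)`` where the truth
    summary is computed by the same estimators on the exact kinematics,
    so differences isolate the imaging + segmentation error.
    """
    truth = build_scene(config)
    stack = render_ring_stack(truth)
    _, measured, _ = analyze_ring_stack(
        stack, pixel_size=config.pixel_size,
        frame_interval=config.frame_interval)
    truth_series = geometry.series_from_truth(truth)
    geometry.compute_metrics(truth_series)
    truth_summary = geometry.summarize_closure(truth_series)
    return measured, truth_summary, truth
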
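"""End-to-end orchestration: load -> motion -> fluctuation -> render -> classify.

``run_analyze`` is the programmatic equivalent of the ``fluctmap
analyze`` command: it executes every stage, writes the maps, the
overlay and a machine-readable summary JSON, and returns the summary.
Outputs are deterministic for a fixed config and inputs (no timestamps
in the summary; timings go to the log only).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import cine_io, detection, fluctuation, rendering
from .config import AnalysisConfig
from .errors import InputError

logger = logging.getLogger("fluctmap")

__all__ = ["run_analyze"]


def _stage(name: str):
    """Decorate exceptions with the pipeline stage they came from."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
                logger.error("stage %s: failed: %s", name, exc)
            else:
                logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_analyze(config: AnalysisConfig) -> dict[str, Any]:
    """Run the full analysis described by ``config``; return the summary dict."""
    warnings: list[str] = []

    with _stage("load"):
        cine = cine_io.load_cine(config.input,
                                 pixel_spacing_override=config.pixel_spacing_mm,
                                 frame_rate_override=config.frame_rate_hz)
        roi = cine_io.load_roi(config.roi, cine.frame_shape)
        lesion = None
        if config.lesion_mask is not None:
            lesion = cine_io.load_mask(config.lesion_mask, cine.frame_shape)
            # guidance: the analysis needs comparison tissue around the
            # lesion of about the lesion's own area
            if roi.n_pixels < 2 * int(lesion.sum()):
                msg = (f"ROI area ({roi.n_pixels} px) is smaller than twice the "
                       f"lesion area ({int(lesion.sum())} px); include more "
                       "surrounding tissue for a reliable comparison")
                warnings.append(msg)
                logger.warning(msg)

    with _stage("fluctuation"):
        fmap = fluctuation.fluctuation_map(
            cine, roi,
            window_mm=config.window_mm,
            neighborhood_mm=config.neighborhood_mm,
            n_frames=config.n_frames,
            motion=config.motion,
            search_radius_px=config.search_radius_px,
            subpixel=config.subpixel,
        )

    with _stage("render"):
        ov = rendering.render_overlay(
            cine.frames[0], fmap.level, fmap.valid,
            alpha=config.alpha, palette=config.palette,
            display_min_level=config.display_min_level)

    call = None
    if lesion is not None:
        with _stage("classify"):
            call = detection.classify_lesion(
                fmap, lesion,
                level_threshold=config.level_threshold,
                min_fraction=config.min_fraction,
                min_component_px=config.min_component_px)

    outputs: dict[str, str] = {}
    if config.out_prefix is not None:
        with _stage("write"):
            prefix = Path(config.out_prefix)
            prefix.parent.mkdir(parents=True, exist_ok=True)
            outputs["score"] = str(cine_io.save_score_map(
                fmap.score, prefix.with_name(prefix.name + "_score.npy")))
            outputs["level"] = str(cine_io.save_level_png(
                fmap.level, prefix.with_name(prefix.name + "_level.png")))
            outputs["valid"] = str(prefix.with_name(prefix.name + "_valid.npy"))
            np.save(outputs["valid"], fmap.valid)
            outputs["overlay"] = str(cine_io.save_overlay_png(
                ov.rgb, prefix.with_name(prefix.name + "_overlay.png")))

    v = fmap.valid
    summary: dict[str, Any] = {
        "config": config.to_json_dict(),
        "input": {
            "n_frames_total": cine.n_frames,
            "frame_shape": list(cine.frame_shape),
            "frame_rate_hz": cine.frame_rate_hz,
            "pixel_spacing_mm": list(cine.pixel_spacing_mm),
            "container": cine.source_meta.get("container"),
        },
        "map": {
            "params": fmap.params,
            "n_valid_px": int(v.sum()),
            "roi_px": roi.n_pixels,
            "mean_score": float(fmap.score[v].mean()) if v.any() else None,
            "max_score": float(fmap.score[v].max()) if v.any() else None,
            "max_level": int(fmap.level[v].max()) if v.any() else None,
        },
        "call": call.to_json_dict() if call is not None else None,
        "outputs": outputs,
        "warnings": warnings,
    }
    if config.out_prefix is not None:
        spath = Path(config.out_prefix).with_name(Path(config.out_prefix).name + "_summary.json")
        spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
        outputs["summary"] = str(spath)
    return summary
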
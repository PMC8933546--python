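"""255-gradation colour mapping and overlay composition.

Levels encode the degree of fluctuation: level 0 (stable speckle) is
blue, rising through cyan-green and yellow to red at 255 (complete
frame-to-frame decorrelation).  The anchor colours are fixed so the
mapping is deterministic and bit-exact:

    0 -> (0, 0, 255)   blue
    85 -> (0, 255, 128) cyan-green
    170 -> (255, 255, 0) yellow
    255 -> (255, 0, 0)  red

with linear interpolation between anchors.  Only the semantic direction
(blue = stable, yellow/red = fluctuating) is dictated by the method;
the exact anchors are this package's choice and alternative palettes
can be registered.

By default colour is drawn only where level >= ``display_min_level``
(32, i.e. more than ~12.5 % decorrelation per frame interval) so quiet
tissue shows plain grayscale; this is a display choice, independent of
the lesion-call thresholds in :mod:`fluctmap.detection`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["ColorOverlay", "palette_lut", "colorize", "overlay",
           "render_overlay", "DEFAULT_DISPLAY_MIN_LEVEL"]

DEFAULT_DISPLAY_MIN_LEVEL = 32

_PALETTES: dict[str, tuple[tuple[int, ...], tuple[tuple[int, int, int], ...]]] = {
    "blue_red": ((0, 85, 170, 255),
                 ((0, 0, 255), (0, 255, 128), (255, 255, 0), (255, 0, 0))),
}


@dataclass
class ColorOverlay:
    """RGB image with the overlay parameters that produced it."""

    rgb: np.ndarray          # (rows, cols, 3) uint8
    alpha_used: float
    palette_name: str

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=np.uint8)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise InputError("overlay rgb must be (rows, cols, 3)")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def palette_lut(name: str = "blue_red") -> np.ndarray:
    """256 x 3 uint8 lookup table for a registered palette."""
    try:
        anchors, colors = _PALETTES[name]
    except KeyError as exc:
        raise InputError(f"unknown palette {name!r}; known: {sorted(_PALETTES)}") from exc
    levels = np.arange(256)
    lut = np.stack([
        _round_half_up(np.interp(levels, anchors, [c[ch] for c in colors]))
        for ch in range(3)
    ], axis=1)
    return lut.astype(np.uint8)


def colorize(level: np.ndarray, valid: np.ndarray | None = None,
             palette: str = "blue_red") -> np.ndarray:
    """Map a 0-255 level image through the palette; invalid pixels -> black."""
    level = np.asarray(level)
    if level.min() < 0 or level.max() > 255:
        raise InputError("level values must lie in 0-255")
    rgb = palette_lut(palette)[level.astype(np.int64)]
    if valid is not None:
        rgb = rgb.copy()
        rgb[~np.asarray(valid, dtype=bool)] = 0
    return rgb


def overlay(frame: np.ndarray, colors: np.ndarray, alpha: float,
            show_mask: np.ndarray | None = None,
            palette_name: str = "blue_red") -> ColorOverlay:
    """Alpha-blend colours onto a grayscale frame on the shown pixels.

    ``out = alpha * color + (1 - alpha) * gray`` on shown pixels (rounded
    half up per channel); pure grayscale elsewhere.  ``frame`` is [0, 1]
    intensity.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InputError(f"alpha must lie in [0, 1], got {alpha}")
    frame = np.asarray(frame, dtype=np.float64)
    colors = np.asarray(colors)
    if colors.shape[:2] != frame.shape or colors.shape[2] != 3:
        raise InputError("colors must be (rows, cols, 3) matching the frame")
    gray = _round_half_up(255.0 * frame)
    out = np.repeat(gray[..., None], 3, axis=2)
    show = (np.ones(frame.shape, dtype=bool) if show_mask is None
            else np.asarray(show_mask, dtype=bool))
    blended = _round_half_up(alpha * colors.astype(np.float64)
                             + (1.0 - alpha) * gray[..., None])
    out[show] = blended[show]
    return ColorOverlay(np.clip(out, 0, 255), float(alpha), palette_name)


def render_overlay(frame: np.ndarray, level: np.ndarray, valid: np.ndarray,
                   alpha: float = 0.5, palette: str = "blue_red",
                   display_min_level: int = DEFAULT_DISPLAY_MIN_LEVEL) -> ColorOverlay:
    """Standard presentation: colour only valid pixels at/above the display floor."""
    show = np.asarray(valid, dtype=bool) & (np.asarray(level) >= display_min_level)
    colors = colorize(level, valid, palette)
    return overlay(frame, colors, alpha, show, palette)
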
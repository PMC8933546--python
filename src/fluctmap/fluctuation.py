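"""Local temporal cross-correlation and the fluctuation map.

The central statistic: for every analysis point and every consecutive
frame pair (n-1, n), the Pearson correlation coefficient R of the two
frames' intensities over a small square window (about 2 mm) centred on
the point,

    R = sum_ij (I_n - mean I_n)(I_{n-1} - mean I_{n-1})
        / sqrt(sum_ij (I_n - mean I_n)^2) / sqrt(sum_ij (I_{n-1} - mean I_{n-1})^2),

where the sums run over the window and the means are window means.
Static, well-correlated speckle gives R near 1; speckle that
decorrelates between frames (the "fluttering" lesion interior, where
slow internal blood motion rearranges the scatterers) gives lower R.

The per-pair R values are aggregated into a *degree of coincidence*
C(p): the mean of clamp(R, 0, 1) over all frame pairs and over a small
spatial neighbourhood of p.  Negative R carries no more evidence of
coincidence than R = 0, hence the clamp; the 0-1 range then maps onto
the 255-level colour scale.  The *degree of fluctuation* is F = 1 - C,
quantized as level = round(255 * F): blue (low level) marks stable
tissue, yellow-to-red (high level) marks strong frame-to-frame
decorrelation.

Windows are never padded: a point whose window leaves the frame, or
whose window has zero intensity variance in either frame, is marked
invalid rather than filled with fabricated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .cine_io import CineLoop, RoiMask
from .errors import InputError
from . import motion as _motion

__all__ = [
    "RMap",
    "FluctuationMap",
    "mm_to_radius_px",
    "local_xcorr_pair",
    "coincidence_map",
    "fluctuation_map",
]

_VAR_EPS = 1e-12  # window variance below this is treated as zero (invalid R)


@dataclass
class RMap:
    """Per-pixel cross-correlation R for each consecutive frame pair.

    ``r[t]`` holds R between frames t and t+1; ``valid`` is false where
    a window left the frame, lacked support, or had zero variance.
    """

    r: np.ndarray          # (T-1, rows, cols)
    valid: np.ndarray      # same shape, bool
    window_radius_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r.shape != self.valid.shape or self.r.ndim != 3:
            raise InputError("RMap r/valid must be matching 3D arrays")


@dataclass
class FluctuationMap:
    """The method's central output: per-pixel fluctuation in [0, 1].

    score
        Degree of fluctuation F = 1 - C.
    level
        round(255 * F), the 255-gradation colour index.
    coincidence
        Degree of coincidence C.
    valid
        Pixels with at least one valid contributing R sample, inside
        the ROI.
    params
        Effective analysis settings (window/neighbourhood radii, frame
        budget, motion settings) for provenance.
    """

    score: np.ndarray
    level: np.ndarray
    coincidence: np.ndarray
    valid: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        self.level = np.asarray(self.level, dtype=np.int64)
        self.coincidence = np.asarray(self.coincidence, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {self.score.shape, self.level.shape, self.coincidence.shape, self.valid.shape}
        if len(shapes) != 1:
            raise InputError("FluctuationMap component shapes differ")
        v = self.valid
        if v.any():
            if self.score[v].min() < 0 or self.score[v].max() > 1:
                raise InputError("score outside [0, 1] on valid pixels")
            if self.level[v].min() < 0 or self.level[v].max() > 255:
                raise InputError("level outside 0-255 on valid pixels")


def quantize_level(score: np.ndarray) -> np.ndarray:
    """0-255 gradation index: round(255 * score), half away from zero."""
    return np.floor(255.0 * np.asarray(score, dtype=np.float64) + 0.5).astype(np.int64)


def mm_to_radius_px(extent_mm: float, spacing_mm: tuple[float, float]) -> tuple[int, int]:
    """Per-axis window radius for a physical extent.

    ``extent_mm`` is the full window width in mm; the radius on each axis
    is round(extent / (2 * spacing)), at least 1, so the full width
    2r + 1 px is always odd and spans approximately ``extent_mm``.
    """
    if extent_mm <= 0:
        raise InputError(f"window extent must be > 0 mm, got {extent_mm}")
    # half-up rounding, consistent with level quantization
    return tuple(max(1, int(extent_mm / (2.0 * s) + 0.5)) for s in spacing_mm)  # type: ignore


def _window_sums(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Sum of ``img`` over the centred window at every pixel (zero-padded)."""
    n = size[0] * size[1]
    return ndimage.uniform_filter(img, size=size, mode="constant", cval=0.0) * n


def _support_mask(shape: tuple[int, int], radius: tuple[int, int]) -> np.ndarray:
    """Pixels whose full window lies inside the frame (no padding)."""
    rows, cols = shape
    rr, rc = radius
    m = np.zeros(shape, dtype=bool)
    if rows > 2 * rr and cols > 2 * rc:
        m[rr:rows - rr, rc:cols - rc] = True
    return m


def local_xcorr_pair(frame_prev: np.ndarray, frame_curr: np.ndarray,
                     window_radius_px: int | tuple[int, int],
                     roi: RoiMask | np.ndarray | None = None,
                     valid_prev: np.ndarray | None = None,
                     valid_curr: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed Pearson R between two frames at every analysis point.

    Returns ``(r, valid)``.  A point is valid when its window is fully
    supported by the frame, every window pixel is valid in both frames
    (when validity masks are given), both windows have nonzero variance,
    and the point lies in the ROI.
    """
    if isinstance(window_radius_px, int):
        radius = (window_radius_px, window_radius_px)
    else:
        radius = (int(window_radius_px[0]), int(window_radius_px[1]))
    if radius[0] < 1 or radius[1] < 1:
        raise InputError(f"window_radius_px must be >= 1, got {window_radius_px}")
    a = np.asarray(frame_prev, dtype=np.float64)
    b = np.asarray(frame_curr, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise InputError("frames must be matching 2D arrays")
    size = (2 * radius[0] + 1, 2 * radius[1] + 1)
    n = size[0] * size[1]

    s_a = _window_sums(a, size)
    s_b = _window_sums(b, size)
    s_aa = _window_sums(a * a, size)
    s_bb = _window_sums(b * b, size)
    s_ab = _window_sums(a * b, size)

    cov = s_ab - s_a * s_b / n
    var_a = s_aa - s_a * s_a / n
    var_b = s_bb - s_b * s_b / n

    valid = _support_mask(a.shape, radius)
    if valid_prev is not None or valid_curr is not None:
        both = np.ones(a.shape, dtype=bool)
        if valid_prev is not None:
            both &= np.asarray(valid_prev, dtype=bool)
        if valid_curr is not None:
            both &= np.asarray(valid_curr, dtype=bool)
        # every pixel of the window must be valid in both frames
        valid &= ndimage.minimum_filter(both, size=size, mode="constant", cval=False)
    valid &= (var_a > _VAR_EPS) & (var_b > _VAR_EPS)
    if roi is not None:
        mask = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
        valid &= mask

    r = np.zeros(a.shape, dtype=np.float64)
    denom = np.sqrt(var_a[valid]) * np.sqrt(var_b[valid])
    r[valid] = np.clip(cov[valid] / denom, -1.0, 1.0)
    return r, valid


def cross_correlation_stack(cine: CineLoop, roi: RoiMask | np.ndarray,
                            window_radius_px: int | tuple[int, int],
                            frame_valid: np.ndarray | None = None) -> RMap:
    """R for every consecutive frame pair of a loop."""
    T = cine.n_frames
    rs = []
    vs = []
    for t in range(1, T):
        vp = frame_valid[t - 1] if frame_valid is not None else None
        vc = frame_valid[t] if frame_valid is not None else None
        r, v = local_xcorr_pair(cine.frames[t - 1], cine.frames[t],
                                window_radius_px, roi, vp, vc)
        rs.append(r)
        vs.append(v)
    radius = ((window_radius_px, window_radius_px)
              if isinstance(window_radius_px, int) else tuple(window_radius_px))
    return RMap(np.stack(rs), np.stack(vs), radius)  # type: ignore[arg-type]


def coincidence_map(rmap: RMap,
                    neighborhood_radius_px: int | tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Degree of coincidence: spatio-temporal mean of clamp(R, 0, 1).

    At each pixel p, C(p) averages clamp(r, 0, 1) over every valid
    sample within the (2*radius+1)^2 spatial neighbourhood of p across
    all frame pairs.  Pixels with no valid contributing sample are
    invalid.  Returns ``(coincidence, valid)``.
    """
    if isinstance(neighborhood_radius_px, int):
        radius = (neighborhood_radius_px, neighborhood_radius_px)
    else:
        radius = (int(neighborhood_radius_px[0]), int(neighborhood_radius_px[1]))
    if radius[0] < 0 or radius[1] < 0:
        raise InputError(f"neighborhood radius must be >= 0, got {neighborhood_radius_px}")
    if rmap.r.shape[0] < 1:
        raise InputError("RMap has no frame pairs")
    size = (2 * radius[0] + 1, 2 * radius[1] + 1)
    clamped = np.clip(rmap.r, 0.0, 1.0) * rmap.valid
    num = np.zeros(rmap.r.shape[1:], dtype=np.float64)
    den = np.zeros_like(num)
    for t in range(rmap.r.shape[0]):
        num += _window_sums(clamped[t], size)
        den += _window_sums(rmap.valid[t].astype(np.float64), size)
    valid = den > 0.5
    c = np.zeros_like(num)
    c[valid] = np.clip(num[valid] / den[valid], 0.0, 1.0)
    return c, valid


def fluctuation_map(cine: CineLoop, roi: RoiMask,
                    window_mm: float = 2.0,
                    neighborhood_mm: float = 2.0,
                    n_frames: int = 70,
                    motion: bool = True,
                    search_radius_px: int = 8,
                    subpixel: bool = False) -> FluctuationMap:
    """Full analysis: motion cancellation, per-pair R, coincidence, F, level.

    Uses the first ``n_frames`` frames of the loop (70 frames at 20 fps,
    i.e. 3.5 s, by default).  Window and neighbourhood extents are given
    in millimetres and converted per axis via the pixel spacing.
    """
    if cine.n_frames < n_frames:
        raise InputError(
            f"insufficient frames: clip has {cine.n_frames}, analysis needs {n_frames}")
    if n_frames < 2:
        raise InputError(f"n_frames must be >= 2, got {n_frames}")
    sub = CineLoop(cine.frames[:n_frames], cine.frame_rate_hz,
                   cine.pixel_spacing_mm, dict(cine.source_meta))
    w_radius = mm_to_radius_px(window_mm, sub.pixel_spacing_mm)
    n_radius = mm_to_radius_px(neighborhood_mm, sub.pixel_spacing_mm)

    track = None
    frame_valid = None
    if motion:
        track = _motion.estimate_motion(sub, roi, search_radius_px, subpixel)
        sub, frame_valid = _motion.compensate(sub, track)

    rmap = cross_correlation_stack(sub, roi, w_radius, frame_valid)
    c, c_valid = coincidence_map(rmap, n_radius)
    valid = c_valid & roi.mask
    if not valid.any():
        raise InputError("ROI empty after validity intersection")
    score = np.zeros_like(c)
    score[valid] = 1.0 - c[valid]
    coincidence = np.zeros_like(c)
    coincidence[valid] = c[valid]
    level = np.zeros(score.shape, dtype=np.int64)
    level[valid] = quantize_level(score[valid])
    params = {
        "window_mm": window_mm,
        "neighborhood_mm": neighborhood_mm,
        "window_radius_px": list(w_radius),
        "neighborhood_radius_px": list(n_radius),
        "n_frames": n_frames,
        "frame_rate_hz": sub.frame_rate_hz,
        "pixel_spacing_mm": list(sub.pixel_spacing_mm),
        "motion": motion,
        "search_radius_px": search_radius_px if motion else None,
        "subpixel": subpixel if motion else None,
        "track": track.to_json_dict() if track is not None else None,
    }
    return FluctuationMap(score, level, coincidence, valid, params)
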
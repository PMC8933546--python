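"""Bulk-motion estimation and cancellation for cine loops.

Breathing and cardiac pulsation translate the whole region of interest
between frames; left in place, that translation decorrelates the speckle
and masquerades as genuine internal fluctuation.  The model here is a
single rigid 2D translation per frame, estimated by exhaustive
block-matching: the ROI patch of frame 0 is correlated (Pearson NCC)
against every integer shift of frame t within a search radius, and the
best shift is subtracted before the fluctuation analysis.

Frame 0 is the fixed reference for every frame (not the previous frame)
so that estimation errors cannot accumulate over the few-second clip.
Ties in the correlation surface are broken toward the smallest
displacement magnitude, then smallest row, then smallest col, which
makes the estimator fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cine_io import CineLoop, RoiMask
from .errors import InputError

__all__ = ["MotionTrack", "estimate_motion", "compensate"]


@dataclass
class MotionTrack:
    """Per-frame 2D displacement of the scene relative to frame 0.

    ``displacements[t] = (d_row, d_col)`` means the content that sits at
    pixel p in frame 0 sits at pixel p + d in frame t.  Compensation
    therefore samples frame t at p + d.
    """

    displacements: np.ndarray  # (T, 2) float
    search_radius_px: int
    subpixel: bool

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 2:
            raise InputError("displacements must have shape (T, 2)")
        if not np.allclose(self.displacements[0], 0.0):
            raise InputError("displacements[0] must be (0, 0)")
        if np.abs(self.displacements).max() > self.search_radius_px + 0.5 + 1e-9:
            raise InputError("displacement exceeds search radius")

    def __len__(self) -> int:
        return self.displacements.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "displacements": self.displacements.tolist(),
            "search_radius_px": self.search_radius_px,
            "subpixel": self.subpixel,
        }


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Vertex offset of the parabola through (-1, cm), (0, c0), (1, cp)."""
    denom = cm - 2.0 * c0 + cp
    if denom >= -1e-12:  # flat or non-concave: keep the integer peak
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_motion(cine: CineLoop, roi: RoiMask,
                    search_radius_px: int = 8,
                    subpixel: bool = False) -> MotionTrack:
    """Estimate the per-frame rigid translation of the ROI relative to frame 0.

    Exhaustive integer-shift search maximizing the Pearson correlation
    between the ROI pixels of frame 0 and the correspondingly shifted
    pixels of frame t; optional 1D parabolic interpolation of the
    correlation peak in each axis for subpixel refinement.

    Raises
    ------
    InputError
        If the search window does not fit in the frame or the ROI patch
        of frame 0 has zero intensity variance (correlation undefined).
    """
    s = int(search_radius_px)
    if s < 1:
        raise InputError(f"search_radius_px must be >= 1, got {search_radius_px}")
    r0, c0, r1, c1 = roi.bounding_box
    rows, cols = cine.frame_shape
    if r0 - s < 0 or c0 - s < 0 or r1 + s > rows or c1 + s > cols:
        raise InputError(
            f"ROI bounding box {roi.bounding_box} plus search radius {s} "
            f"does not fit in frame {cine.frame_shape}")

    rr, cc = np.nonzero(roi.mask)
    ref = cine.frames[0][rr, cc]
    a = ref - ref.mean()
    na = np.sqrt((a * a).sum())
    if na < 1e-12:
        raise InputError("ROI patch of frame 0 has zero intensity variance")

    T = cine.n_frames
    shifts = [(dr, dc) for dr in range(-s, s + 1) for dc in range(-s, s + 1)]
    shifts.sort(key=lambda d: (d[0] * d[0] + d[1] * d[1], d[0], d[1]))
    ncc = np.full((T, 2 * s + 1, 2 * s + 1), -np.inf)
    best = np.full((T, 2), 0.0)
    best_ncc = np.full(T, -np.inf)
    frames = cine.frames
    for dr, dc in shifts:
        # pixels of frame t at the ROI coordinates shifted by (dr, dc), all frames at once
        b = frames[:, rr + dr, cc + dc]
        b = b - b.mean(axis=1, keepdims=True)
        nb = np.sqrt((b * b).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            val = (b @ a) / (na * nb)
        val = np.where(nb < 1e-12, -np.inf, val)
        ncc[:, dr + s, dc + s] = val
        improved = val > best_ncc  # strict: earlier (smaller) shifts win ties
        best[improved] = (dr, dc)
        best_ncc = np.where(improved, val, best_ncc)

    disp = best.astype(np.float64)
    if subpixel:
        for t in range(1, T):
            dr, dc = int(best[t, 0]), int(best[t, 1])
            ir, ic = dr + s, dc + s
            if 0 < ir < 2 * s and np.isfinite(ncc[t, ir - 1, ic]) and np.isfinite(ncc[t, ir + 1, ic]):
                disp[t, 0] += _parabolic_offset(ncc[t, ir - 1, ic], ncc[t, ir, ic], ncc[t, ir + 1, ic])
            if 0 < ic < 2 * s and np.isfinite(ncc[t, ir, ic - 1]) and np.isfinite(ncc[t, ir, ic + 1]):
                disp[t, 1] += _parabolic_offset(ncc[t, ir, ic - 1], ncc[t, ir, ic], ncc[t, ir, ic + 1])
    disp[0] = 0.0
    return MotionTrack(disp, s, bool(subpixel))


def compensate(cine: CineLoop, track: MotionTrack) -> tuple[CineLoop, np.ndarray]:
    """Cancel the tracked translation: resample each frame back onto frame 0.

    Integer displacements use exact nearest-neighbour indexing; fractional
    ones use bilinear interpolation.  Returns the compensated loop and a
    per-frame boolean validity stack marking pixels whose source sample
    fell inside the frame; downstream stages intersect it.
    """
    if len(track) != cine.n_frames:
        raise InputError(f"track length {len(track)} != frame count {cine.n_frames}")
    rows, cols = cine.frame_shape
    if np.abs(track.displacements).max() >= min(rows, cols):
        raise InputError("displacement exceeds frame size")
    out = np.empty_like(cine.frames)
    valid = np.empty(cine.frames.shape, dtype=bool)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    for t in range(cine.n_frames):
        dr, dc = track.displacements[t]
        if dr == 0.0 and dc == 0.0:
            out[t] = cine.frames[t]
            valid[t] = True
            continue
        sr, sc = rr + dr, cc + dc
        ok = (sr >= 0) & (sr <= rows - 1) & (sc >= 0) & (sc <= cols - 1)
        if float(dr).is_integer() and float(dc).is_integer():
            isr = np.clip(sr.astype(np.int64), 0, rows - 1)
            isc = np.clip(sc.astype(np.int64), 0, cols - 1)
            out[t] = cine.frames[t][isr, isc]
        else:
            out[t] = ndimage.map_coordinates(cine.frames[t], [sr, sc], order=1,
                                             mode="constant", cval=0.0)
        out[t][~ok] = 0.0
        valid[t] = ok
    comp = CineLoop(out, cine.frame_rate_hz, cine.pixel_spacing_mm,
                    {**cine.source_meta, "motion_compensated": True})
    return comp, valid
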
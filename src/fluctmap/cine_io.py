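"""Reading and writing ultrasound cine loops, ROIs and derived maps.

A cine loop is an ordered stack of grayscale frames together with its
physical calibration: the frame rate in Hz and the pixel spacing in
mm/pixel.  Calibration is carried through the whole pipeline because the
analysis window is specified in millimetres.  Conventions used everywhere
in this package: 0-based indices, (row, col) axis order, rectangles are
half-open ``[row0, row1) x [col0, col1)``.

Supported input containers: multiframe DICOM, directories of equally
sized PNG/TIFF frames, multipage TIFF stacks, raw ``.npy`` numeric
stacks, and (when the imageio ffmpeg plugin is installed) AVI/MP4 video.
Intensities are min-max normalized to [0, 1] per clip at load time; the
local correlation statistic downstream is invariant to positive linear
intensity maps, so this normalization cannot change results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "CineLoop",
    "RoiMask",
    "load_cine",
    "load_roi",
    "load_mask",
    "rasterize_polygon",
    "save_score_map",
    "load_score_map",
    "save_level_png",
    "save_overlay_png",
    "save_overlay_video",
]

_FRAME_EXTS = {".png", ".tif", ".tiff"}
_VIDEO_EXTS = {".avi", ".mp4", ".mov", ".mkv"}

# ITU-R BT.601 luma weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class CineLoop:
    """A grayscale cine loop with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, rows, cols)
        Intensities in [0, 1] (after load-time normalization), float64.
    frame_rate_hz : float
        Acquisition frame rate, frames per second.
    pixel_spacing_mm : tuple of float
        (row_spacing, col_spacing) in mm/pixel.
    source_meta : dict
        Free-form provenance record (file path, container, DICOM tags...).
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_spacing_mm: tuple[float, float]
    source_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InputError(f"frames must be 3D (T, rows, cols), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise InputError(f"a cine loop needs >= 2 frames, got {self.frames.shape[0]}")
        if not np.all(np.isfinite(self.frames)):
            raise InputError("frames contain non-finite values")
        if self.frames.min() < -1e-12 or self.frames.max() > 1 + 1e-12:
            raise InputError("frame intensities must lie in [0, 1] after normalization")
        if not self.frame_rate_hz > 0:
            raise InputError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        rs, cs = self.pixel_spacing_mm
        if not (rs > 0 and cs > 0):
            raise InputError(f"pixel spacings must be > 0, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = (float(rs), float(cs))
        self.frame_rate_hz = float(self.frame_rate_hz)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class RoiMask:
    """Boolean analysis region on the frame grid.

    ``bounding_box`` is the tight half-open box (row0, col0, row1, col1)
    of the true pixels; it is recomputed, never trusted from the caller.
    """

    mask: np.ndarray
    bounding_box: tuple[int, int, int, int] = (0, 0, 0, 0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError("ROI mask must be 2D")
        if not self.mask.any():
            raise InputError("ROI mask has no true pixels")
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        self.bounding_box = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_rect(cls, row0: int, col0: int, row1: int, col1: int,
                  frame_shape: tuple[int, int]) -> "RoiMask":
        rows, cols = frame_shape
        if not (0 <= row0 < row1 <= rows and 0 <= col0 < col1 <= cols):
            raise InputError(
                f"rectangle ({row0},{col0},{row1},{col1}) outside frame {frame_shape}")
        mask = np.zeros(frame_shape, dtype=bool)
        mask[row0:row1, col0:col1] = True
        return cls(mask)


def _normalize(stack: np.ndarray) -> np.ndarray:
    """Per-clip min-max normalization to [0, 1]; constant clips map to 0."""
    stack = np.asarray(stack, dtype=np.float64)
    lo, hi = stack.min(), stack.max()
    if hi > lo:
        return (stack - lo) / (hi - lo)
    return np.zeros_like(stack)


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return np.asarray(frame[..., :3], dtype=np.float64) @ _LUMA
    raise InputError(f"cannot interpret frame of shape {frame.shape} as grayscale or RGB(A)")


def _finish(stack: np.ndarray, rate: float | None, spacing: tuple[float, float] | None,
            meta: dict[str, Any]) -> CineLoop:
    if rate is None:
        raise InputError(
            "frame rate unavailable from the container; pass frame_rate_override")
    if spacing is None:
        raise InputError(
            "pixel spacing unavailable from the container; pass pixel_spacing_override "
            "(the mm-sized analysis window requires mm/pixel calibration)")
    return CineLoop(_normalize(stack), rate, spacing, meta)


def _load_frame_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
    if len(files) < 2:
        raise InputError(f"{path}: found {len(files)} frame image(s), need >= 2")
    frames = []
    for f in files:
        frames.append(_to_gray(iio.imread(f)))
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise InputError(f"{path}: inconsistent frame shapes {sorted(shapes)}")
    return np.stack(frames)


def _load_dicom(path: Path) -> tuple[np.ndarray, float | None, tuple[float, float] | None,
                                     dict[str, Any]]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2:
        raise InputError(f"{path}: single-frame DICOM, need a multiframe cine")
    if arr.ndim == 4:  # color multiframe
        arr = np.stack([_to_gray(fr) for fr in arr])
    rate: float | None = None
    if getattr(ds, "FrameTime", None):
        rate = 1000.0 / float(ds.FrameTime)
    elif getattr(ds, "CineRate", None):
        rate = float(ds.CineRate)
    elif getattr(ds, "RecommendedDisplayFrameRate", None):
        rate = float(ds.RecommendedDisplayFrameRate)
    spacing: tuple[float, float] | None = None
    if getattr(ds, "PixelSpacing", None):
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    meta = {"sop_class": str(getattr(ds, "SOPClassUID", "")),
            "n_frames_tag": int(getattr(ds, "NumberOfFrames", arr.shape[0]))}
    return np.asarray(arr, dtype=np.float64), rate, spacing, meta


def _load_video(path: Path) -> tuple[np.ndarray, float | None]:
    import imageio.v3 as iio

    try:
        meta = iio.immeta(path, plugin="FFMPEG")
        raw = iio.imread(path, plugin="FFMPEG")
    except Exception as exc:  # plugin missing or unreadable file
        raise InputError(
            f"cannot read video {path}: {exc}. AVI/MP4 support requires the "
            "imageio-ffmpeg plugin (install extra 'fluctmap[video]')") from exc
    frames = np.stack([_to_gray(fr) for fr in raw])
    rate = float(meta["fps"]) if "fps" in meta else None
    return frames, rate


def load_cine(path: str | Path,
              pixel_spacing_override: tuple[float, float] | None = None,
              frame_rate_override: float | None = None) -> CineLoop:
    """Load a cine loop from any supported container.

    Overrides take precedence over container metadata.  Missing
    calibration (frame rate or pixel spacing) with no override is an
    error: the analysis window is defined in millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    meta: dict[str, Any] = {"path": str(path)}
    rate: float | None = None
    spacing: tuple[float, float] | None = None

    if path.is_dir():
        stack = _load_frame_dir(path)
        meta["container"] = "frame_dir"
    else:
        ext = path.suffix.lower()
        if ext in {".dcm", ".dicom"} or ext == "":
            stack, rate, spacing, dmeta = _load_dicom(path)
            meta.update(dmeta)
            meta["container"] = "dicom"
        elif ext == ".npy":
            stack = np.load(path)
            if stack.ndim != 3:
                raise InputError(f"{path}: raw stack must be 3D, got ndim={stack.ndim}")
            meta["container"] = "npy"
        elif ext in {".tif", ".tiff"}:
            import tifffile

            stack = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
            if stack.ndim == 4:
                stack = np.stack([_to_gray(fr) for fr in stack])
            if stack.ndim != 3:
                raise InputError(f"{path}: TIFF stack must be 3D, got ndim={stack.ndim}")
            meta["container"] = "tiff"
        elif ext in _VIDEO_EXTS:
            stack, rate = _load_video(path)
            meta["container"] = "video"
        else:
            raise InputError(f"unsupported cine container: {path}")

    if stack.shape[0] < 2:
        raise InputError(f"{path}: cine needs >= 2 frames, got {stack.shape[0]}")
    if frame_rate_override is not None:
        rate = float(frame_rate_override)
    if pixel_spacing_override is not None:
        spacing = (float(pixel_spacing_override[0]), float(pixel_spacing_override[1]))
    return _finish(stack, rate, spacing, meta)


def rasterize_polygon(vertices: Sequence[Sequence[float]],
                      frame_shape: tuple[int, int]) -> np.ndarray:
    """Fill a polygon on the pixel grid by the even-odd (crossing-number) rule.

    A pixel (r, c) is inside when a ray from its center crosses the
    polygon boundary an odd number of times.  Vertices are 0-based
    (row, col) pixel coordinates and may be fractional.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InputError("polygon needs >= 3 (row, col) vertices")
    rows, cols = frame_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    inside = np.zeros(frame_shape, dtype=bool)
    n = verts.shape[0]
    for k in range(n):
        r1, c1 = verts[k]
        r2, c2 = verts[(k + 1) % n]
        if r1 == r2:
            continue
        crosses = (r1 > rr) != (r2 > rr)
        # col coordinate where the edge crosses the pixel's row
        with np.errstate(invalid="ignore"):
            c_at = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (cc < c_at)
    return inside


def load_roi(path: str | Path, frame_shape: tuple[int, int]) -> RoiMask:
    """Load an ROI specification (JSON rect or polygon) as a boolean mask."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such ROI file: {path}")
    try:
        spec = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON: {exc}") from exc
    return roi_from_spec(spec, frame_shape)


def roi_from_spec(spec: Mapping[str, Any], frame_shape: tuple[int, int]) -> RoiMask:
    kind = spec.get("type")
    if kind == "rect":
        try:
            r0, c0, r1, c1 = (int(spec[k]) for k in ("row0", "col0", "row1", "col1"))
        except KeyError as exc:
            raise InputError(f"rect ROI missing key {exc}") from exc
        return RoiMask.from_rect(r0, c0, r1, c1, frame_shape)
    if kind == "polygon":
        verts = np.asarray(spec.get("vertices", []), dtype=np.float64)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise InputError("polygon ROI needs >= 3 vertices")
        rows, cols = frame_shape
        if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
                or verts[:, 0].max() > rows or verts[:, 1].max() > cols):
            raise InputError("polygon vertices outside frame bounds")
        mask = rasterize_polygon(verts, frame_shape)
        if not mask.any():
            raise InputError("polygon rasterized to an empty mask")
        return RoiMask(mask)
    raise InputError(f"unknown ROI type {kind!r} (expected 'rect' or 'polygon')")


def load_mask(path: str | Path, frame_shape: tuple[int, int]) -> np.ndarray:
    """Load a boolean pixel mask from .npy, .png or ROI-style JSON."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask file: {path}")
    ext = path.suffix.lower()
    if ext == ".npy":
        mask = np.load(path)
    elif ext == ".png":
        import imageio.v3 as iio

        mask = iio.imread(path)
        if mask.ndim == 3:
            mask = mask[..., 0]
    elif ext == ".json":
        return load_roi(path, frame_shape).mask
    else:
        raise InputError(f"unsupported mask container: {path}")
    mask = np.asarray(mask) != 0
    if mask.shape != tuple(frame_shape):
        raise InputError(f"mask shape {mask.shape} != frame shape {tuple(frame_shape)}")
    return mask


# ---------------------------------------------------------------------------
# writers

def save_score_map(score: np.ndarray, path: str | Path) -> Path:
    """Save a floating score map losslessly (.npy or float TIFF by extension)."""
    path = Path(path)
    score = np.asarray(score, dtype=np.float64)
    ext = path.suffix.lower()
    if ext == ".npy":
        np.save(path, score)
    elif ext in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), score)
    else:
        raise InputError(f"score maps are saved as .npy or .tif, got {path}")
    return path


def load_score_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such map file: {path}")
    ext = path.suffix.lower()
    if ext == ".npy":
        return np.asarray(np.load(path), dtype=np.float64)
    if ext in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    raise InputError(f"unsupported score map container: {path}")


def save_level_png(level: np.ndarray, path: str | Path) -> Path:
    """Save a 0-255 quantized level map as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    level = np.asarray(level)
    if level.min() < 0 or level.max() > 255:
        raise InputError("level map values must lie in 0-255")
    path = Path(path)
    iio.imwrite(path, level.astype(np.uint8))
    return path


def save_overlay_png(rgb: np.ndarray, path: str | Path) -> Path:
    import imageio.v3 as iio

    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise InputError("overlay image must be (rows, cols, 3)")
    path = Path(path)
    iio.imwrite(path, rgb.astype(np.uint8))
    return path


def save_overlay_video(rgb_frames: np.ndarray, path: str | Path, fps: float) -> Path:
    """Save an RGB overlay cine as video (requires the imageio ffmpeg plugin)."""
    import imageio

    path = Path(path)
    try:
        with imageio.get_writer(str(path), fps=fps) as w:
            for fr in np.asarray(rgb_frames).astype(np.uint8):
                w.append_data(fr)
    except Exception as exc:
        raise InputError(
            f"cannot write video {path}: {exc}. Video output requires the "
            "imageio-ffmpeg plugin (install extra 'fluctmap[video]')") from exc
    return path
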
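"""Seeded synthetic B-mode speckle cine loops with known ground truth.

No patient data ships with this package, so every pipeline stage is
exercised on simulated clips built from a first-order speckle model:

* background speckle is the envelope magnitude of complex circular
  white Gaussian noise convolved with a separable Gaussian point-spread
  function (axial x lateral sigma in pixels) -- fully developed speckle
  whose point intensities are Rayleigh distributed;
* inside each "fluttering" region the complex scatterer field evolves
  as a per-pixel AR(1) process, z_t = rho * z_{t-1} + sqrt(1 - rho^2) * w_t,
  with fresh white noise w_t, so the per-frame field correlation is
  exactly rho (one interpretable knob tied directly to the quantity the
  analysis measures); outside, the field is frozen at z_0;
* an optional global sinusoidal translation along the axial (row) axis,
  rounded to integer pixels, emulates cardiac pulsation -- the known
  false-positive mechanism that motion compensation must cancel.
  Translation is realised by cropping a moving window from a padded
  field, so it is exact with no wraparound or border artefacts;
* optional additive Gaussian intensity noise, then clipping to [0, 1].

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .cine_io import CineLoop
from .errors import InputError

__all__ = [
    "FlutterRegion",
    "SyntheticSpec",
    "disc_mask",
    "simulate",
    "complex_fields",
    "speckle_envelope",
    "make_fixture_suite",
    "PRESETS",
]


@dataclass
class FlutterRegion:
    """A region whose speckle decorrelates: per-frame AR(1) correlation rho."""

    mask: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not 0.0 <= self.rho <= 1.0:
            raise InputError(f"rho must lie in [0, 1], got {self.rho}")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic clip.

    Defaults mirror the acquisition this package targets: 70 frames at
    20 fps (3.5 s) of 96 x 96 px at 0.2 mm/px, PSF sigma 1.5 px axial x
    2.0 px lateral.
    """

    shape: tuple[int, int, int] = (70, 96, 96)
    pixel_spacing_mm: tuple[float, float] = (0.2, 0.2)
    frame_rate_hz: float = 20.0
    psf_sigma_px: tuple[float, float] = (1.5, 2.0)
    flutter_regions: list[FlutterRegion] = field(default_factory=list)
    pulsation: tuple[float, float] | None = None  # (amplitude_px, frequency_hz)
    translations_px: np.ndarray | None = None     # explicit (T, 2) integer shifts
    noise_sigma: float = 0.0
    log_compress: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        T, R, C = self.shape
        if T < 2 or R < 1 or C < 1:
            raise InputError(f"invalid clip shape {self.shape}")
        for reg in self.flutter_regions:
            if reg.mask.shape != (R, C):
                raise InputError(
                    f"flutter mask shape {reg.mask.shape} != frame shape {(R, C)}")
        if self.translations_px is not None:
            tr = np.asarray(self.translations_px)
            if tr.shape != (T, 2):
                raise InputError(f"translations_px must have shape {(T, 2)}")
            if not np.array_equal(tr[0], (0, 0)):
                raise InputError("translations_px[0] must be (0, 0)")
            self.translations_px = tr.astype(np.int64)
        if self.noise_sigma < 0:
            raise InputError("noise_sigma must be >= 0")


def disc_mask(frame_shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Boolean disc on the pixel grid (inclusive boundary)."""
    rr, cc = np.mgrid[0:frame_shape[0], 0:frame_shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _shifts(spec: SyntheticSpec) -> np.ndarray:
    T = spec.shape[0]
    if spec.translations_px is not None:
        return np.asarray(spec.translations_px, dtype=np.int64)
    if spec.pulsation is None:
        return np.zeros((T, 2), dtype=np.int64)
    amp, freq = spec.pulsation
    t = np.arange(T) / spec.frame_rate_hz
    d_row = np.floor(amp * np.sin(2.0 * np.pi * freq * t) + 0.5).astype(np.int64)
    return np.stack([d_row, np.zeros_like(d_row)], axis=1)


def complex_fields(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Raw (pre-PSF) complex scatterer fields on the padded grid.

    Returns ``(fields, pad)`` where ``fields`` has shape
    (T, rows + 2 pad, cols + 2 pad); the frame-0 crop starts at
    ``(pad, pad)``.  Exposed so that the AR(1) temporal statistics can
    be checked directly against the rho knob.
    """
    T, R, C = spec.shape
    shifts = _shifts(spec)
    pad = int(np.abs(shifts).max())
    rng = np.random.default_rng(spec.seed)
    gr, gc = R + 2 * pad, C + 2 * pad
    z = (rng.standard_normal((gr, gc)) + 1j * rng.standard_normal((gr, gc)))
    fields = np.empty((T, gr, gc), dtype=np.complex128)
    fields[0] = z
    # flutter masks live in frame-0 coordinates -> offset by pad on the grid
    regions = []
    for reg in spec.flutter_regions:
        m = np.zeros((gr, gc), dtype=bool)
        m[pad:pad + R, pad:pad + C] = reg.mask
        regions.append((m, reg.rho))
    for t in range(1, T):
        w = rng.standard_normal((gr, gc)) + 1j * rng.standard_normal((gr, gc))
        z = z.copy()
        for m, rho in regions:
            z[m] = rho * fields[t - 1][m] + np.sqrt(1.0 - rho ** 2) * w[m]
        fields[t] = z
    return fields, np.array(pad)


def _envelope(field: np.ndarray, psf_sigma: tuple[float, float]) -> np.ndarray:
    sm = gaussian_filter(field.real, psf_sigma) + 1j * gaussian_filter(field.imag, psf_sigma)
    return np.abs(sm)


def speckle_envelope(shape: tuple[int, int], psf_sigma_px: tuple[float, float] = (1.5, 2.0),
                     seed: int = 0) -> np.ndarray:
    """One raw speckle envelope frame (no normalization): Rayleigh point stats."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return _envelope(z, psf_sigma_px)


def simulate(spec: SyntheticSpec) -> tuple[CineLoop, np.ndarray]:
    """Render a synthetic cine loop.

    Returns the loop and the ground-truth flutter mask (union of the
    flutter regions, in frame coordinates).
    """
    T, R, C = spec.shape
    fields, pad = complex_fields(spec)
    pad = int(pad)
    shifts = _shifts(spec)
    frames = np.empty((T, R, C), dtype=np.float64)
    for t in range(T):
        env = _envelope(fields[t], spec.psf_sigma_px)
        # shifts are scene displacements: content at p in frame 0 sits at
        # p + d in frame t, so frame t is the window cropped at pad - d
        dr, dc = shifts[t]
        frames[t] = env[pad - dr:pad - dr + R, pad - dc:pad - dc + C]
    lo, hi = frames.min(), frames.max()
    frames = (frames - lo) / (hi - lo) if hi > lo else np.zeros_like(frames)
    if spec.log_compress:
        frames = np.log1p(100.0 * frames) / np.log1p(100.0)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        frames = frames + rng.normal(0.0, spec.noise_sigma, frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    truth = np.zeros((R, C), dtype=bool)
    for reg in spec.flutter_regions:
        truth |= reg.mask
    loop = CineLoop(frames, spec.frame_rate_hz, spec.pixel_spacing_mm,
                    {"synthetic": True, "seed": spec.seed,
                     "pulsation": list(spec.pulsation) if spec.pulsation else None,
                     "noise_sigma": spec.noise_sigma,
                     "rhos": [reg.rho for reg in spec.flutter_regions]})
    return loop, truth


# ---------------------------------------------------------------------------
# canonical fixture suite

_DISC_CENTER = (48.0, 48.0)
_DISC_RADIUS = 18.0
_ROI_RECT = {"type": "rect", "row0": 16, "col0": 16, "row1": 80, "col1": 80}
_PULSATION = (2.0, 1.0)   # 2 px amplitude at 1 Hz
_FLUTTER_RHO = 0.9
_NOISE = 0.01


def preset_spec(name: str, seed: int = 0) -> SyntheticSpec:
    """Spec for one of the canonical presets: static, flutter, pulsation, both."""
    disc = disc_mask((96, 96), _DISC_CENTER, _DISC_RADIUS)
    if name == "static":
        return SyntheticSpec(seed=seed)
    if name == "flutter":
        return SyntheticSpec(flutter_regions=[FlutterRegion(disc, _FLUTTER_RHO)],
                             noise_sigma=_NOISE, seed=seed)
    if name == "pulsation":
        return SyntheticSpec(pulsation=_PULSATION, seed=seed)
    if name == "both":
        return SyntheticSpec(flutter_regions=[FlutterRegion(disc, _FLUTTER_RHO)],
                             pulsation=_PULSATION, noise_sigma=_NOISE, seed=seed)
    raise InputError(f"unknown preset {name!r}; known: static, flutter, pulsation, both")


PRESETS = ("static", "flutter", "pulsation", "both")


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical four-clip test suite to ``out_dir``.

    Each preset yields a raw float32 stack (``<name>.npy``), a
    rectangular ROI JSON, the ground-truth flutter mask and the lesion
    (disc) mask as ``.npy`` booleans, plus a ``manifest.json`` recording
    every parameter and per-clip seed.  Regeneration with the same seed
    is bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disc = disc_mask((96, 96), _DISC_CENTER, _DISC_RADIUS)
    manifest: dict = {"seed": int(seed), "clips": {}}
    for i, name in enumerate(PRESETS):
        clip_seed = int(seed) * 1000 + i
        spec = preset_spec(name, seed=clip_seed)
        loop, truth = simulate(spec)
        np.save(out / f"{name}.npy", loop.frames.astype(np.float32))
        np.save(out / f"{name}_flutter_mask.npy", truth)
        np.save(out / f"{name}_lesion_mask.npy", disc)
        (out / f"{name}_roi.json").write_text(json.dumps(_ROI_RECT))
        manifest["clips"][name] = {
            "file": f"{name}.npy",
            "seed": clip_seed,
            "shape": list(spec.shape),
            "frame_rate_hz": spec.frame_rate_hz,
            "pixel_spacing_mm": list(spec.pixel_spacing_mm),
            "psf_sigma_px": list(spec.psf_sigma_px),
            "rho": _FLUTTER_RHO if spec.flutter_regions else None,
            "pulsation": list(spec.pulsation) if spec.pulsation else None,
            "noise_sigma": spec.noise_sigma,
            "roi": f"{name}_roi.json",
            "flutter_mask": f"{name}_flutter_mask.npy",
            "lesion_mask": f"{name}_lesion_mask.npy",
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
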
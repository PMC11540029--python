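"""Per-channel convolution rendering of color-signed defocus stimuli.

Each RGB frame is decomposed into its R, G and B channels, each channel is
convolved with its condition-specific PSF kernel, and the channels are
recombined.  Convolution is done in linear light by default (decode an
assumed gamma of 2.2, convolve, re-encode), with reflect padding so that
unit-sum kernels conserve mean luminance without dark vignettes.  The
reference condition is an exact passthrough.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.signal import fftconvolve

from . import __version__
from .chromatic_model import ChannelPrimaries, ChromaticEyeModel, Condition, DefocusPlan
from .psf_engine import PSFKernel, channel_psf

__all__ = [
    "DisplayGeometry",
    "RenderOptions",
    "plate_scale",
    "condition_kernels",
    "render_frame",
    "render_video",
]

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class DisplayGeometry:
    """Projection geometry of the stimulus display."""

    width_px: int = 1920
    height_px: int = 1080
    fov_horizontal_deg: float = 28.5
    fov_vertical_deg: float = 17.0
    viewing_distance_m: float = 5.1
    frame_rate_hz: float = 24.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "fov_horizontal_deg",
            "fov_vertical_deg",
            "viewing_distance_m",
            "frame_rate_hz",
            "bit_depth",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


def plate_scale(display: DisplayGeometry) -> tuple[float, float]:
    """Angular pixel pitch (arcmin/px), horizontal then vertical.

    Small-angle convention: 60 * fov / pixels per axis.
    """
    return (
        60.0 * display.fov_horizontal_deg / display.width_px,
        60.0 * display.fov_vertical_deg / display.height_px,
    )


@dataclass(frozen=True)
class RenderOptions:
    """Rendering policy knobs.

    linearize : decode gamma before convolving (physical-light default).
    gamma     : display transfer exponent assumed when linearizing.
    boundary  : padding mode handed to numpy.pad.
    """

    linearize: bool = True
    gamma: float = 2.2
    boundary: str = "reflect"


def condition_kernels(
    condition: Condition | str,
    display: DisplayGeometry | None = None,
    primaries: ChannelPrimaries | None = None,
    model: ChromaticEyeModel | None = None,
    magnitude: float = 3.0,
    pupil_diameter_mm: float = 4.0,
) -> tuple[DefocusPlan, dict[str, PSFKernel]]:
    """Build the defocus plan and the per-channel kernels for a condition."""
    from .chromatic_model import build_defocus_plan

    display = display or DisplayGeometry()
    primaries = primaries or ChannelPrimaries()
    sx, sy = plate_scale(display)
    plan = build_defocus_plan(condition, primaries, model, magnitude)
    kernels = {
        ch: channel_psf(
            plan,
            ch,
            primaries,
            pupil_diameter_mm=pupil_diameter_mm,
            plate_scale_x=sx,
            plate_scale_y=sy,
            model=model,
        )
        for ch in ("red", "green", "blue")
    }
    return plan, kernels


def _check_frame(frame: np.ndarray, display: DisplayGeometry) -> None:
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"frame must be HxWx3, got shape {frame.shape}")
    if np.issubdtype(frame.dtype, np.integer):
        vmax = 2**display.bit_depth - 1
        if frame.min() < 0 or frame.max() > vmax:
            raise ValueError(f"integer frame values must lie in [0, {vmax}]")
    else:
        if not np.isfinite(frame).all():
            raise ValueError("float frame contains non-finite values")


def _check_kernel_scale(
    kernel: PSFKernel, display: DisplayGeometry, channel: str
) -> None:
    sx, sy = plate_scale(display)
    if not (
        math.isclose(kernel.plate_scale_x, sx, rel_tol=1e-6)
        and math.isclose(kernel.plate_scale_y, sy, rel_tol=1e-6)
    ):
        raise ValueError(
            f"{channel} kernel plate scale ({kernel.plate_scale_x:.4f}, "
            f"{kernel.plate_scale_y:.4f}) arcmin/px does not match the display "
            f"geometry ({sx:.4f}, {sy:.4f}) arcmin/px"
        )


def convolve_channel(
    channel: np.ndarray, kernel: PSFKernel, boundary: str = "reflect"
) -> np.ndarray:
    """Convolve one float channel with a kernel, padded per ``boundary``."""
    if kernel.identity:
        return channel.astype(float, copy=True)
    k = kernel.values
    py, px = k.shape[0] // 2, k.shape[1] // 2
    padded = np.pad(channel.astype(float), ((py, py), (px, px)), mode=boundary)
    out = fftconvolve(padded, k, mode="same")
    return out[py : py + channel.shape[0], px : px + channel.shape[1]]


def render_frame(
    frame: np.ndarray,
    plan: DefocusPlan,
    kernels: Mapping[str, PSFKernel],
    display: DisplayGeometry | None = None,
    options: RenderOptions | None = None,
) -> tuple[np.ndarray, dict]:
    """Render one RGB frame under a defocus plan.

    Returns ``(rendered, stats)`` where ``stats`` counts values clipped
    during re-quantization.  Integer input comes back at the same bit depth;
    float input (assumed in [0, 1]) comes back as float without
    quantization.  The reference condition returns an unchanged copy.
    """
    display = display or DisplayGeometry()
    options = options or RenderOptions()
    _check_frame(frame, display)

    if plan.condition is Condition.REFERENCE:
        return frame.copy(), {"clipped": 0, "passthrough": True}

    is_int = np.issubdtype(frame.dtype, np.integer)
    vmax = 2**display.bit_depth - 1
    work = frame.astype(float) / vmax if is_int else frame.astype(float)
    if options.linearize:
        work = np.power(np.clip(work, 0.0, None), options.gamma)

    out = np.empty_like(work)
    for ch, idx in CHANNEL_INDEX.items():
        kernel = kernels[ch]
        _check_kernel_scale(kernel, display, ch)
        out[:, :, idx] = convolve_channel(work[:, :, idx], kernel, options.boundary)

    if options.linearize:
        out = np.power(np.clip(out, 0.0, None), 1.0 / options.gamma)

    clipped = int(np.count_nonzero((out < 0) | (out > 1)))
    out = np.clip(out, 0.0, 1.0)
    if is_int:
        out = np.rint(out * vmax).astype(frame.dtype)
    return out, {"clipped": clipped, "passthrough": False}


def _frame_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def render_video(
    frames_dir: str | Path,
    out_dir: str | Path,
    condition: Condition | str,
    display: DisplayGeometry | None = None,
    primaries: ChannelPrimaries | None = None,
    model: ChromaticEyeModel | None = None,
    magnitude: float = 3.0,
    pupil_diameter_mm: float = 4.0,
    options: RenderOptions | None = None,
) -> dict:
    """Render every frame of an image-sequence directory.

    Kernels are computed once and applied to all frames; the run fails
    atomically if any input frame is unreadable or has inconsistent
    dimensions.  A JSON run log (defocus plan, plate scale, per-frame
    content hashes, clip counts) is written next to the output frames and
    returned.
    """
    import imageio.v3 as iio

    frames_dir = Path(frames_dir)
    out_dir = Path(out_dir)
    display = display or DisplayGeometry()
    primaries = primaries or ChannelPrimaries()
    options = options or RenderOptions()

    paths = sorted(
        p for p in frames_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF frames found in {frames_dir}")

    # Validate everything up front so failure cannot leave partial output.
    frames = []
    shape = None
    for p in paths:
        try:
            arr = np.asarray(iio.imread(p))
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise OSError(f"unreadable frame {p.name}: {exc}") from exc
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] > 3:
            arr = arr[:, :, :3]
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"frame {p.name} has shape {arr.shape}, expected {shape}"
            )
        frames.append(arr)

    plan, kernels = condition_kernels(
        condition, display, primaries, model, magnitude, pupil_diameter_mm
    )
    sx, sy = plate_scale(display)

    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "software": f"chromadefocus {__version__}",
        "condition": Condition.parse(condition).value,
        "defocus_plan": plan.to_dict(primaries),
        "plate_scale_arcmin": {"x": sx, "y": sy},
        "pupil_diameter_mm": pupil_diameter_mm,
        "options": {
            "linearize": options.linearize,
            "gamma": options.gamma,
            "boundary": options.boundary,
        },
        "kernel_shapes": {ch: list(k.values.shape) for ch, k in kernels.items()},
        "frames": [],
    }
    for p, arr in zip(paths, frames):
        rendered, stats = render_frame(arr, plan, kernels, display, options)
        out_path = out_dir / p.name
        iio.imwrite(out_path, rendered)
        log["frames"].append(
            {
                "name": p.name,
                "input_sha256": _frame_hash(arr),
                "output_sha256": _frame_hash(rendered),
                "clipped": stats["clipped"],
            }
        )
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return log
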
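"""Radially averaged amplitude spectra of frame channels.

Characterizes frames by the mean log normalized amplitude as a function of
log spatial frequency (cycles/degree), the standard description of natural
image statistics (broadband ~1/f amplitude falloff).  The same machinery
serves as the oracle for blur attenuation: the bin-wise amplitude ratio of
a rendered channel to its original tracks the modulation transfer function
of the kernel that produced it.

Conventions: a Hann window suppresses edge leakage before the transform;
amplitudes are normalized by the DC component; bins are log-spaced (30 per
decade) between 0.1 cyc/deg and the coarser-axis Nyquist; with non-square
angular pixels every transform sample is mapped to its true radial
frequency before binning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RadialSpectrum",
    "radial_amplitude_spectrum",
    "aggregate_spectra",
    "attenuation_ratio",
    "spectral_slope",
]

BINS_PER_DECADE = 30
F_MIN_CPD = 0.1


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged amplitude spectrum of one or more frames."""

    frequency_cpd: np.ndarray  # bin centers, cycles/degree, strictly increasing
    amplitude: np.ndarray  # mean normalized amplitude per bin (linear scale)
    n_frames: int = 1
    degenerate: bool = False  # True for a constant (DC-only) input

    @property
    def log_amplitude(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log10(self.amplitude)

    def to_frame(self):
        """Tidy table (frequency, log amplitude, n) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frequency_cpd": self.frequency_cpd,
                "log10_amplitude": self.log_amplitude,
                "n_frames": self.n_frames,
            }
        )


def _log_bins(nyquist_cpd: float) -> np.ndarray:
    n = int(np.ceil(np.log10(nyquist_cpd / F_MIN_CPD) * BINS_PER_DECADE))
    return np.logspace(np.log10(F_MIN_CPD), np.log10(nyquist_cpd), n + 1)


def _radial_frequencies(shape: tuple[int, int], plate_scale_x: float, plate_scale_y: float):
    h, w = shape
    fy = np.fft.fftfreq(h, d=plate_scale_y / 60.0)  # cycles/degree
    fx = np.fft.fftfreq(w, d=plate_scale_x / 60.0)
    return np.hypot(*np.meshgrid(fy, fx, indexing="ij"))


def _binned_amplitude(
    image: np.ndarray, plate_scale_x: float, plate_scale_y: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    win = np.outer(np.hanning(img.shape[0]), np.hanning(img.shape[1]))
    spec = np.abs(np.fft.fft2(img * win))
    dc = spec[0, 0]
    degenerate = False
    if dc <= 0 or np.ptp(img) == 0:
        # Constant image: amplitude beyond DC is undefined; report zeros.
        degenerate = True
        norm = np.zeros_like(spec)
    else:
        norm = spec / dc
    fr = _radial_frequencies(img.shape, plate_scale_x, plate_scale_y)
    nyquist = min(30.0 / plate_scale_x, 30.0 / plate_scale_y)
    edges = _log_bins(nyquist)
    idx = np.digitize(fr.ravel(), edges) - 1
    # The Hann window's DC mainlobe spans +/-2 frequency steps; samples
    # inside it carry mean-luminance leakage, not image structure.
    df_max = max(
        1.0 / (img.shape[0] * plate_scale_y / 60.0),
        1.0 / (img.shape[1] * plate_scale_x / 60.0),
    )
    keep = (idx >= 0) & (idx < len(edges) - 1) & (fr.ravel() >= 2.5 * df_max)
    sums = np.bincount(idx[keep], weights=norm.ravel()[keep], minlength=len(edges) - 1)
    counts = np.bincount(idx[keep], minlength=len(edges) - 1)
    # Empirical bin centers: sparse low-frequency bins hold few discrete
    # transform samples, so the mean sample frequency represents a bin far
    # better than its geometric center.
    fsums = np.bincount(idx[keep], weights=fr.ravel()[keep], minlength=len(edges) - 1)
    good = counts > 0
    centers = fsums[good] / counts[good]
    amp = sums[good] / counts[good]
    return centers, amp, degenerate


def radial_amplitude_spectrum(
    image: np.ndarray, plate_scale_x: float, plate_scale_y: float
) -> RadialSpectrum:
    """Radially averaged, DC-normalized amplitude spectrum of one channel.

    ``plate_scale_*`` are arcmin per pixel; frequencies come back in
    cycles/degree.  A constant image yields all-zero amplitudes with the
    ``degenerate`` flag set.
    """
    f, a, degenerate = _binned_amplitude(image, plate_scale_x, plate_scale_y)
    return RadialSpectrum(frequency_cpd=f, amplitude=a, degenerate=degenerate)


def aggregate_spectra(
    frames: Sequence[np.ndarray],
    channel: int | str,
    plate_scale_x: float,
    plate_scale_y: float,
) -> RadialSpectrum:
    """Bin-wise average spectrum of one channel across frames.

    ``channel`` is 0/1/2 or "red"/"green"/"blue"; frames must share
    dimensions.
    """
    if isinstance(channel, str):
        channel = {"red": 0, "green": 1, "blue": 2}[channel]
    frames = list(frames)
    if not frames:
        raise ValueError("aggregate_spectra needs at least one frame")
    shape = frames[0].shape
    amps = []
    freqs = None
    for fr in frames:
        if fr.shape != shape:
            raise ValueError(f"frame shape {fr.shape} does not match {shape}")
        chan = fr[:, :, channel] if fr.ndim == 3 else fr
        f, a, _ = _binned_amplitude(chan, plate_scale_x, plate_scale_y)
        freqs = f
        amps.append(a)
    return RadialSpectrum(
        frequency_cpd=freqs,
        amplitude=np.mean(amps, axis=0),
        n_frames=len(frames),
    )


def attenuation_ratio(
    original_frames: Sequence[np.ndarray],
    rendered_frames: Sequence[np.ndarray],
    channel: int | str,
    plate_scale_x: float,
    plate_scale_y: float,
    gamma: float | None = 2.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise amplitude ratio rendered/original for one channel.

    Frames are decoded to linear light first (``gamma=None`` for already
    linear data) since blur combines linear intensities.  For frames
    rendered through a unit-sum kernel the ratio tracks the kernel's MTF
    below Nyquist.  Returns ``(frequencies_cpd, ratio)``.
    """
    original_frames = list(original_frames)
    rendered_frames = list(rendered_frames)
    if len(original_frames) != len(rendered_frames) or not original_frames:
        raise ValueError("need equal, nonzero numbers of original and rendered frames")

    def linearize(frames):
        out = []
        for fr in frames:
            arr = np.asarray(fr, dtype=float)
            if np.issubdtype(np.asarray(fr).dtype, np.integer):
                arr = arr / 255.0
            if gamma is not None:
                arr = np.power(np.clip(arr, 0.0, None), gamma)
            out.append(arr)
        return out

    orig = aggregate_spectra(
        linearize(original_frames), channel, plate_scale_x, plate_scale_y
    )
    rend = aggregate_spectra(
        linearize(rendered_frames), channel, plate_scale_x, plate_scale_y
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rend.amplitude / orig.amplitude
    return orig.frequency_cpd, ratio


def spectral_slope(
    spectrum: RadialSpectrum, f_lo: float = 0.5, f_hi: float = 10.0
) -> float:
    """Least-squares slope of log amplitude vs. log frequency on [f_lo, f_hi]."""
    m = (
        (spectrum.frequency_cpd >= f_lo)
        & (spectrum.frequency_cpd <= f_hi)
        & (spectrum.amplitude > 0)
    )
    if m.sum() < 3:
        raise ValueError("too few usable bins for a slope fit")
    x = np.log10(spectrum.frequency_cpd[m])
    y = np.log10(spectrum.amplitude[m])
    return float(np.polyfit(x, y, 1)[0])
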
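"""Defocused and diffraction-limited point-spread functions via Fourier optics.

A channel's retinal point-spread function (PSF) is computed as the squared
modulus of the Fourier transform of the generalized pupil function: a
circular aperture of the given diameter carrying a quadratic defocus phase

    W(rho) = W20 * (rho / R)^2,      W20 = D * R^2 / 2

with D the defocus in diopters and R the pupil radius.  The field is
evaluated on a fine angular grid (several samples per display pixel and per
Airy radius), squared, then box-integrated onto the display pixel grid and
renormalized to unit sum.  With zero defocus this reproduces the Airy
pattern, whose first dark ring sits at angular radius 1.22 * lambda / d.

Pure-defocus PSFs depend on |D| only and are radially symmetric; the sign is
nevertheless carried on the kernel's provenance so that models adding
odd-symmetric aberrations later stay sign-aware.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chromatic_model import (
    ChannelPrimaries,
    ChromaticEyeModel,
    Condition,
    DefocusPlan,
    relative_lca,
)

__all__ = [
    "PupilParams",
    "PSFKernel",
    "AliasingError",
    "defocus_wavefront_coefficient",
    "monochromatic_psf",
    "channel_psf",
    "kernel_mtf",
    "equivalent_blur_diameter",
    "encircled_energy_diameter",
]

ARCMIN_PER_RAD = 180.0 * 60.0 / math.pi

# Hard cap on pupil-plane samples per axis before declaring the request
# unresolvable without aliasing.
MAX_PUPIL_SAMPLES = 4096


class AliasingError(RuntimeError):
    """Raised when the pupil phase cannot be Nyquist-sampled within limits."""


@dataclass(frozen=True)
class PupilParams:
    """Circular pupil with pure defocus: diameter (mm), wavelength (nm),
    defocus (diopters, positive = myopic)."""

    diameter_mm: float
    wavelength_nm: float
    defocus_D: float = 0.0

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0):
            raise ValueError(f"pupil diameter must be positive, got {self.diameter_mm}")
        if not (self.wavelength_nm > 0):
            raise ValueError(f"wavelength must be positive, got {self.wavelength_nm}")
        if not math.isfinite(self.defocus_D):
            raise ValueError("defocus must be finite")

    @property
    def airy_radius_arcmin(self) -> float:
        """Angular radius of the first Airy zero, 1.22 * lambda / d."""
        return 1.22 * (self.wavelength_nm * 1e-9) / (self.diameter_mm * 1e-3) * ARCMIN_PER_RAD

    @property
    def geometric_blur_arcmin(self) -> float:
        """Geometric blur-circle angular diameter, |D| * d, in arcmin."""
        return abs(self.defocus_D) * (self.diameter_mm * 1e-3) * ARCMIN_PER_RAD


@dataclass(frozen=True)
class PSFKernel:
    """Discrete unit-sum 2-D blur kernel on the display pixel grid.

    ``values`` has odd side lengths with the optical axis at the central
    pixel; ``plate_scale_*`` give the angular pixel pitch in arcmin/px.
    ``identity`` flags the no-convolution (reference) case.
    """

    values: np.ndarray
    plate_scale_x: float
    plate_scale_y: float
    provenance: str = "unspecified"
    params: PupilParams | None = None
    identity: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] % 2 == 0 or v.shape[1] % 2 == 0:
            raise ValueError(f"kernel must be 2-D with odd side lengths, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("kernel entries must be nonnegative")
        s = v.sum()
        if not math.isclose(s, 1.0, abs_tol=1e-6):
            raise ValueError(f"kernel must sum to 1 within 1e-6, got {s}")
        object.__setattr__(self, "values", v)

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)

    def export(self, path: str | Path) -> None:
        """Write the kernel as CSV plus a JSON sidecar with its metadata."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",")
        meta = {
            "plate_scale_x_arcmin": self.plate_scale_x,
            "plate_scale_y_arcmin": self.plate_scale_y,
            "provenance": self.provenance,
            "identity": self.identity,
            "shape": list(self.values.shape),
        }
        if self.params is not None:
            meta["pupil"] = {
                "diameter_mm": self.params.diameter_mm,
                "wavelength_nm": self.params.wavelength_nm,
                "defocus_D": self.params.defocus_D,
            }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def identity_kernel(plate_scale_x: float, plate_scale_y: float) -> PSFKernel:
    return PSFKernel(
        values=np.ones((1, 1)),
        plate_scale_x=plate_scale_x,
        plate_scale_y=plate_scale_y,
        provenance="identity: no convolution",
        identity=True,
    )


def defocus_wavefront_coefficient(defocus_D: float, pupil_radius_mm: float) -> float:
    """Peak defocus wavefront error W20 at the pupil margin, in micrometers.

    W20 = D * r^2 / 2; linear in defocus, quadratic in pupil radius.
    """
    if not (pupil_radius_mm > 0):
        raise ValueError(f"pupil radius must be positive, got {pupil_radius_mm}")
    if not math.isfinite(defocus_D):
        raise ValueError("defocus must be finite")
    r_m = pupil_radius_mm * 1e-3
    return defocus_D * r_m**2 / 2.0 * 1e6


def _required_pupil_samples(params: PupilParams, theta_max_rad: float) -> int:
    # Highest local spatial frequency across the pupil (cycles/m): the DFT
    # tilt at the largest requested angle plus the defocus phase slope at the
    # pupil margin.  Nyquist needs two samples per cycle.
    lam = params.wavelength_nm * 1e-9
    r = params.diameter_mm * 1e-3 / 2.0
    f_max = (theta_max_rad + abs(params.defocus_D) * r) / lam
    return int(math.ceil(2.0 * f_max * 2.0 * r)) + 1


def default_support(
    params: PupilParams, plate_scale_x: float, plate_scale_y: float
) -> tuple[int, int]:
    """Odd kernel side lengths covering the geometric blur plus two Airy radii."""
    extent = params.geometric_blur_arcmin + 2.0 * params.airy_radius_arcmin
    ny = max(1, int(math.ceil(extent / plate_scale_y)))
    nx = max(1, int(math.ceil(extent / plate_scale_x)))
    return (ny | 1, nx | 1)


def monochromatic_psf(
    params: PupilParams,
    plate_scale_x: float,
    plate_scale_y: float,
    support: int | tuple[int, int] | None = None,
    oversample: int | None = None,
) -> PSFKernel:
    """PSF of a circular pupil with pure defocus, on the display pixel grid.

    Parameters
    ----------
    params : PupilParams
        Pupil diameter, wavelength and defocus.
    plate_scale_x, plate_scale_y : float
        Angular pixel pitch of the target grid, arcmin per pixel.  The two
        axes may differ (non-square angular pixels).
    support : int or (ny, nx), optional
        Odd kernel side lengths.  Default: auto-sized to the geometric blur
        diameter plus two Airy radii.
    oversample : int, optional
        Fine-grid samples per display pixel per axis.  Default: enough to
        put >= 4 samples per pixel and >= 3 per Airy radius.

    Raises
    ------
    AliasingError
        If Nyquist-sampling the pupil phase would need more than
        ``MAX_PUPIL_SAMPLES`` samples per axis.
    ValueError
        If the requested support cannot contain the geometric blur circle.
    """
    if plate_scale_x <= 0 or plate_scale_y <= 0:
        raise ValueError("plate scales must be positive")
    if support is None:
        ny, nx = default_support(params, plate_scale_x, plate_scale_y)
    else:
        if isinstance(support, int):
            ny = nx = support
        else:
            ny, nx = support
        if ny % 2 == 0 or nx % 2 == 0:
            raise ValueError(f"support must be odd, got {(ny, nx)}")
        min_extent = min(nx * plate_scale_x, ny * plate_scale_y)
        if min_extent < params.geometric_blur_arcmin:
            raise ValueError(
                f"support extent {min_extent:.2f} arcmin cannot contain the "
                f"geometric blur circle ({params.geometric_blur_arcmin:.2f} arcmin)"
            )

    if oversample is None:
        finest = min(plate_scale_x, plate_scale_y)
        target = min(finest / 4.0, params.airy_radius_arcmin / 3.0)
        oversample = max(4, int(math.ceil(finest / target)))

    theta_max = (
        max(nx * plate_scale_x, ny * plate_scale_y) / 2.0 * math.sqrt(2.0)
    ) / ARCMIN_PER_RAD
    n_pupil = max(128, _required_pupil_samples(params, theta_max))
    if n_pupil > MAX_PUPIL_SAMPLES:
        raise AliasingError(
            f"pupil sampling needs {n_pupil} samples/axis (> {MAX_PUPIL_SAMPLES}); "
            "reduce defocus, pupil size, or kernel support"
        )

    lam = params.wavelength_nm * 1e-9
    radius = params.diameter_mm * 1e-3 / 2.0
    u = (np.arange(n_pupil) - (n_pupil - 1) / 2.0) * (2.0 * radius / n_pupil)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    rho2 = (uu**2 + vv**2) / radius**2
    aperture = rho2 <= 1.0
    w20_m = defocus_wavefront_coefficient(params.defocus_D, radius * 1e3) * 1e-6
    pupil = np.where(aperture, np.exp(1j * 2.0 * math.pi / lam * w20_m * rho2), 0.0)

    # Fine angular grid: `oversample` samples per display pixel, centered so
    # that fine-block means are box integrals over each display pixel.
    def fine_angles(n_disp: int, scale_arcmin: float) -> np.ndarray:
        n_fine = n_disp * oversample
        step = scale_arcmin / oversample
        return (np.arange(n_fine) - (n_fine - 1) / 2.0) * step / ARCMIN_PER_RAD

    ty = fine_angles(ny, plate_scale_y)
    tx = fine_angles(nx, plate_scale_x)

    # Direct (non-uniform) DFT, separable in the two axes.
    ker_y = np.exp(-2j * math.pi / lam * np.outer(ty, u))
    ker_x = np.exp(-2j * math.pi / lam * np.outer(tx, u))
    field = ker_y @ pupil @ ker_x.T
    intensity = np.abs(field) ** 2

    # Box-integrate oversample x oversample fine samples per display pixel.
    psf = intensity.reshape(ny, oversample, nx, oversample).mean(axis=(1, 3))
    psf = psf / psf.sum()
    # Guard against negative round-off.
    np.clip(psf, 0.0, None, out=psf)
    psf /= psf.sum()

    return PSFKernel(
        values=psf,
        plate_scale_x=plate_scale_x,
        plate_scale_y=plate_scale_y,
        provenance="diffraction-limited" if params.defocus_D == 0 else "defocused",
        params=params,
    )


def channel_psf(
    plan: DefocusPlan,
    channel: str,
    primaries: ChannelPrimaries | None = None,
    pupil_diameter_mm: float = 4.0,
    plate_scale_x: float = 0.890625,
    plate_scale_y: float = 17.0 * 60.0 / 1080.0,
    model: ChromaticEyeModel | None = None,
    support: int | tuple[int, int] | None = None,
) -> PSFKernel:
    """PSF for one color channel under a defocus plan.

    The reference condition returns an identity kernel flagged
    ``identity: no convolution``.  Under CSM/CSH the green channel gets the
    diffraction-limited kernel (zero imposed defocus) at the green primary.
    If the primaries carry a spectral power distribution for the channel,
    the kernel is the SPD-weighted sum of monochromatic PSFs, each
    wavelength's defocus offset by its LCA relative to the channel primary.
    """
    primaries = primaries or ChannelPrimaries()
    if channel not in ("red", "green", "blue"):
        raise ValueError(f"unknown channel {channel!r}")
    if plan.condition is Condition.REFERENCE:
        return identity_kernel(plate_scale_x, plate_scale_y)

    icd = plan.icd(channel)
    primary_nm = primaries.wavelength(channel)
    spd = (primaries.spd or {}).get(channel)
    if spd is None:
        params = PupilParams(pupil_diameter_mm, primary_nm, icd)
        return monochromatic_psf(params, plate_scale_x, plate_scale_y, support)

    model = model or ChromaticEyeModel()
    lca_primary = relative_lca(model, primary_nm)
    comps = [
        (
            PupilParams(
                pupil_diameter_mm,
                wl,
                icd + (relative_lca(model, wl) - lca_primary),
            ),
            weight,
        )
        for wl, weight in spd
    ]
    if support is None:
        shapes = [default_support(p, plate_scale_x, plate_scale_y) for p, _ in comps]
        support = (max(s[0] for s in shapes), max(s[1] for s in shapes))
    acc = np.zeros(support if isinstance(support, tuple) else (support, support))
    for p, weight in comps:
        k = monochromatic_psf(p, plate_scale_x, plate_scale_y, support)
        acc += weight * k.values
    acc /= acc.sum()
    return PSFKernel(
        values=acc,
        plate_scale_x=plate_scale_x,
        plate_scale_y=plate_scale_y,
        provenance="spd-weighted polychromatic",
    )


def kernel_mtf(
    kernel: PSFKernel, n_freq: int = 128, pad_factor: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged modulation transfer function of a kernel.

    Returns ``(frequencies_cpd, mtf)``: the modulus of the kernel's Fourier
    transform, normalized to 1 at zero frequency and radially averaged onto
    linear frequency bins in cycles/degree up to the coarser-axis Nyquist.
    """
    v = kernel.values
    ny, nx = (max(pad_factor * s, 64) for s in v.shape)
    otf = np.fft.fft2(v, s=(ny, nx))
    mod = np.abs(otf)
    mod /= mod[0, 0]
    fy = np.fft.fftfreq(ny, d=kernel.plate_scale_y / 60.0)  # cycles/degree
    fx = np.fft.fftfreq(nx, d=kernel.plate_scale_x / 60.0)
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    nyq = min(30.0 / kernel.plate_scale_x, 30.0 / kernel.plate_scale_y)
    edges = np.linspace(0.0, nyq, n_freq + 1)
    idx = np.digitize(fr.ravel(), edges) - 1
    keep = (idx >= 0) & (idx < n_freq)
    sums = np.bincount(idx[keep], weights=mod.ravel()[keep], minlength=n_freq)
    counts = np.bincount(idx[keep], minlength=n_freq)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        curve = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # DC bin always exists and equals 1 by normalization.
    curve[0] = 1.0
    return centers, curve


def mtf_at(kernel: PSFKernel, freqs_cpd: np.ndarray, n_azimuths: int = 16) -> np.ndarray:
    """Radial MTF of ``kernel`` evaluated exactly at given frequencies.

    Direct evaluation of the kernel's Fourier transform modulus at each
    requested radial frequency, averaged over azimuths in [0, 90 deg] —
    free of the grid interpolation error of :func:`kernel_mtf`, so suitable
    as a tight oracle.
    """
    ny, nx = kernel.values.shape
    cy, cx = kernel.center
    ydeg = (np.arange(ny) - cy) * kernel.plate_scale_y / 60.0
    xdeg = (np.arange(nx) - cx) * kernel.plate_scale_x / 60.0
    out = np.empty(len(np.atleast_1d(freqs_cpd)))
    for i, f in enumerate(np.atleast_1d(freqs_cpd).astype(float)):
        vals = []
        for theta in np.linspace(0.0, math.pi / 2.0, n_azimuths):
            fy, fx = f * math.sin(theta), f * math.cos(theta)
            phase = np.exp(-2j * math.pi * np.add.outer(fy * ydeg, fx * xdeg))
            vals.append(abs(np.sum(kernel.values * phase)))
        out[i] = float(np.mean(vals))
    return out


def _radial_energy(kernel: PSFKernel) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = kernel.values.shape
    cy, cx = kernel.center
    yy = (np.arange(ny) - cy) * kernel.plate_scale_y
    xx = (np.arange(nx) - cx) * kernel.plate_scale_x
    rr = np.hypot(*np.meshgrid(yy, xx, indexing="ij")).ravel()
    order = np.argsort(rr)
    return rr[order], np.cumsum(kernel.values.ravel()[order])


def encircled_energy_diameter(kernel: PSFKernel, fraction: float = 0.9) -> float:
    """Angular diameter (arcmin) of the circle containing ``fraction`` of
    the kernel's energy, centered on the kernel center."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    radii, cum = _radial_energy(kernel)
    i = int(np.searchsorted(cum, fraction))
    i = min(i, len(radii) - 1)
    return 2.0 * radii[i]


def equivalent_blur_diameter(kernel: PSFKernel) -> float:
    """Second-moment equivalent blur diameter, arcmin: 2 * sqrt(2 * var_r)."""
    ny, nx = kernel.values.shape
    cy, cx = kernel.center
    yy = (np.arange(ny) - cy) * kernel.plate_scale_y
    xx = (np.arange(nx) - cx) * kernel.plate_scale_x
    y2, x2 = np.meshgrid(yy**2, xx**2, indexing="ij")
    var = float(np.sum(kernel.values * (y2 + x2)))
    return 2.0 * math.sqrt(var)
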
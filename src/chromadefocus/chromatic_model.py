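"""Ocular longitudinal chromatic aberration and per-channel imposed defocus.

The human eye's refractive error varies with wavelength: short wavelengths
focus in front of long wavelengths (longitudinal chromatic aberration, LCA).
The reduced-eye chromatic dispersion model used here has the form

    D(lambda) = p - q / (lambda - c)        [lambda in micrometers, D in diopters]

with the published constants p = 1.68524 D, q = 0.63346 D*um, c = 0.21410 um,
so that D crosses zero near 589 nm and spans roughly 2 D across the visible
range.

A color-signed stimulus imposes, per display color channel, the computational
defocus (ICD) that makes the retinal image of that channel carry a desired
retinal defocus (DRD), after discounting the defocus the viewer's own LCA
already contributes:

    ICD(lambda) = DRD(lambda) - LCA(lambda)

where LCA is referenced to the in-focus (green, 550 nm) channel.  A
color-signed myopic (CSM) stimulus uses DRD = +3 D in red and blue; a
color-signed hyperopic (CSH) stimulus uses DRD = -3 D; the green channel is
always left sharp (DRD = 0).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Condition",
    "ChromaticEyeModel",
    "ChannelPrimaries",
    "DefocusPlan",
    "refractive_error",
    "relative_lca",
    "build_defocus_plan",
]

# Reduced-eye chromatic dispersion constants (diopters, diopter*um, um).
INDIANA_P = 1.68524
INDIANA_Q = 0.63346
INDIANA_C = 0.21410

CHANNELS = ("red", "green", "blue")


class Condition(str, enum.Enum):
    """Viewing condition: unmodified reference, or color-signed defocus."""

    REFERENCE = "reference"
    CSM = "csm"  # color-signed myopic: simulates +3 D defocus
    CSH = "csh"  # color-signed hyperopic: simulates -3 D defocus

    @classmethod
    def parse(cls, value: "Condition | str") -> "Condition":
        if isinstance(value, Condition):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown condition {value!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class ChromaticEyeModel:
    """Wavelength -> refractive error model for the eye's chromatic defocus.

    Parameters
    ----------
    p : float
        Asymptotic refractive error at long wavelengths, diopters.
    q : float
        Dispersion strength, diopter * micrometers.  Must be positive.
    c : float
        Singularity wavelength, micrometers.  Must sit below every
        wavelength the model is evaluated at.
    reference_wavelength : float
        Wavelength (nm) at which relative LCA is defined to be zero.
    """

    p: float = INDIANA_P
    q: float = INDIANA_Q
    c: float = INDIANA_C
    reference_wavelength: float = 550.0

    def __post_init__(self) -> None:
        if not (self.q > 0):
            raise ValueError(f"q must be positive, got {self.q}")
        if not (0 < self.c < 0.380):
            raise ValueError(
                f"c must lie below the visible range (0 < c < 0.380 um), got {self.c}"
            )

    @property
    def zero_crossing_nm(self) -> float:
        """Wavelength (nm) where the chromatic refractive error is zero."""
        return 1e3 * (self.c + self.q / self.p)

    def refractive_error(self, wavelength_nm: float) -> float:
        return refractive_error(self, wavelength_nm)

    def relative_lca(self, wavelength_nm: float) -> float:
        return relative_lca(self, wavelength_nm)


def _check_wavelength(model: ChromaticEyeModel, wavelength_nm: float) -> float:
    wl = float(wavelength_nm)
    if not math.isfinite(wl):
        raise ValueError(f"wavelength must be finite, got {wavelength_nm!r}")
    wl_um = wl * 1e-3
    if wl_um <= model.c:
        raise ValueError(
            f"wavelength {wl} nm is at or below the model singularity "
            f"({model.c * 1e3:.1f} nm); refractive error is undefined there"
        )
    return wl_um


def refractive_error(model: ChromaticEyeModel, wavelength_nm: float) -> float:
    """Chromatic refractive error D(lambda) in diopters.

    Strictly increasing in wavelength: short wavelengths are more myopic
    (negative), long wavelengths more hyperopic.
    """
    wl_um = _check_wavelength(model, wavelength_nm)
    return model.p - model.q / (wl_um - model.c)


def relative_lca(model: ChromaticEyeModel, wavelength_nm: float) -> float:
    """LCA relative to the model's reference wavelength, in diopters.

    Exactly zero at the reference wavelength.
    """
    return refractive_error(model, wavelength_nm) - refractive_error(
        model, model.reference_wavelength
    )


@dataclass(frozen=True)
class ChannelPrimaries:
    """Nominal wavelengths (nm) of the display's R, G, B primaries.

    ``spd`` optionally carries a spectral power distribution per channel as
    (wavelength_nm, weight) pairs; weights must be nonnegative and are
    normalized to unit sum.
    """

    red_nm: float = 650.0
    green_nm: float = 550.0
    blue_nm: float = 450.0
    spd: Mapping[str, Sequence[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if not (self.blue_nm < self.green_nm < self.red_nm):
            raise ValueError(
                "primaries must be ordered blue < green < red, got "
                f"B={self.blue_nm}, G={self.green_nm}, R={self.red_nm}"
            )
        if self.spd is not None:
            norm: dict[str, tuple[tuple[float, float], ...]] = {}
            for ch, pairs in self.spd.items():
                if ch not in CHANNELS:
                    raise ValueError(f"unknown SPD channel {ch!r}")
                wts = [w for _, w in pairs]
                if any(w < 0 for w in wts):
                    raise ValueError(f"SPD weights for {ch} must be nonnegative")
                total = sum(wts)
                if total <= 0:
                    raise ValueError(f"SPD weights for {ch} sum to zero")
                norm[ch] = tuple((float(wl), float(w) / total) for wl, w in pairs)
            object.__setattr__(self, "spd", norm)

    def wavelength(self, channel: str) -> float:
        return {"red": self.red_nm, "green": self.green_nm, "blue": self.blue_nm}[
            channel
        ]


@dataclass(frozen=True)
class DefocusPlan:
    """Per-channel defocus schedule for one viewing condition.

    ``icd = drd - lca`` holds per channel by construction; all values in
    diopters, with positive = myopic defocus.
    """

    condition: Condition
    drd_per_channel: Mapping[str, float]
    lca_per_channel: Mapping[str, float]
    icd_per_channel: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        icd = {
            ch: self.drd_per_channel[ch] - self.lca_per_channel[ch] for ch in CHANNELS
        }
        object.__setattr__(self, "icd_per_channel", icd)

    def icd(self, channel: str) -> float:
        return self.icd_per_channel[channel]

    def to_dict(self, primaries: ChannelPrimaries | None = None) -> dict:
        """Serializable summary for run logs and frame sidecar metadata."""
        out: dict = {"condition": self.condition.value, "channels": {}}
        for ch in CHANNELS:
            entry = {
                "drd_D": self.drd_per_channel[ch],
                "lca_D": self.lca_per_channel[ch],
                "icd_D": self.icd_per_channel[ch],
            }
            if primaries is not None:
                entry["wavelength_nm"] = primaries.wavelength(ch)
            out["channels"][ch] = entry
        return out


def build_defocus_plan(
    condition: Condition | str,
    primaries: ChannelPrimaries | None = None,
    model: ChromaticEyeModel | None = None,
    magnitude: float = 3.0,
) -> DefocusPlan:
    """Build the per-channel defocus schedule for one condition.

    The desired retinal defocus (DRD) is ``+magnitude`` (CSM) or
    ``-magnitude`` (CSH) at the red and blue primaries and 0 at the green
    primary; the reference condition imposes nothing.  The imposed
    computational defocus follows as ``ICD = DRD - LCA`` with LCA referenced
    to the green (reference) wavelength, so CSM carries more blur in blue
    than red and CSH the reverse.
    """
    condition = Condition.parse(condition)
    primaries = primaries or ChannelPrimaries()
    model = model or ChromaticEyeModel()
    if not (magnitude > 0):
        raise ValueError(f"magnitude must be positive, got {magnitude}")

    sign = {Condition.REFERENCE: 0.0, Condition.CSM: +1.0, Condition.CSH: -1.0}[
        condition
    ]
    drd = {
        "red": sign * magnitude,
        "green": 0.0,
        "blue": sign * magnitude,
    }
    lca = {ch: relative_lca(model, primaries.wavelength(ch)) for ch in CHANNELS}
    if condition is Condition.REFERENCE:
        # Nothing is imposed in the reference case: ICD identically zero.
        lca = {ch: 0.0 for ch in CHANNELS}
    return DefocusPlan(condition=condition, drd_per_channel=drd, lca_per_channel=lca)
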
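"""Seed-deterministic synthetic inputs for every analysis stage.

Three generators stand in for the study's unavailable raw data:

* ``gen_frames`` — natural-like frames with a broadband 1/f-type amplitude
  spectrum (plus gratings, impulses, uniform fields and edge patterns as
  test stimuli) for the rendering and spectral modules;
* ``gen_cohort`` — a pre/post biometry cohort with between-subject baseline
  spread, within-session replicate noise, and configurable per-condition
  true change effects, with axial length composed as AL = ACD + LT + VCD so
  the component bookkeeping holds by construction;
* ``gen_choroid_boundaries`` — choroid boundary traces with spatially
  correlated per-grader noise around a known thickness field.

Default cohort effect sizes and variability mirror the study conditions the
analysis is meant to handle: reference / color-signed myopic (CSM) /
color-signed hyperopic (CSH) sessions with mean changes of order 0.01-0.03
mm in the biometer parameters, subfoveal choroidal thickness baselines of
236 +/- 70 um between subjects and ~7.5 um repeatability within subjects.
Every generator emits a machine-readable truth record so downstream
estimates can be compared with the generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .biometry import ECCENTRICITY_GRID_MM, ChoroidProfile

__all__ = [
    "FrameSpec",
    "CohortSpec",
    "EffectSpec",
    "gen_frames",
    "gen_cohort",
    "gen_choroid_boundaries",
    "paired_test_rejection_mc",
    "STUDY_EFFECTS",
    "NULL_EFFECTS",
]

GAMMA = 2.2
Pattern = Literal["noise1f", "grating", "impulse", "uniform", "edges"]


# ---------------------------------------------------------------------------
# frames


@dataclass(frozen=True)
class FrameSpec:
    """Synthetic frame recipe.

    ``plate_scale_*`` are arcmin/px (defaults match the study display);
    ``slope`` is the log-log amplitude slope of noise1f frames (<= 0);
    ``contrast`` is the RMS contrast of the linear-light pattern;
    ``grating_f0_cpd``/``grating_orientation_deg`` apply to gratings only.
    """

    width: int = 256
    height: int = 256
    pattern: Pattern = "noise1f"
    slope: float = -1.0
    contrast: float = 0.3
    plate_scale_x: float = 60.0 * 28.5 / 1920.0
    plate_scale_y: float = 60.0 * 17.0 / 1080.0
    grating_f0_cpd: float = 5.0
    grating_orientation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.pattern == "noise1f" and self.slope > 0:
            raise ValueError("natural-like frames need slope <= 0")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")


def _encode(linear: np.ndarray) -> np.ndarray:
    """Linear light in [0, 1] -> gamma-encoded 8-bit RGB frame."""
    enc = np.power(np.clip(linear, 0.0, 1.0), 1.0 / GAMMA)
    chan = np.rint(enc * 255.0).astype(np.uint8)
    return np.stack([chan] * 3, axis=-1)


def _noise1f(spec: FrameSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal((spec.height, spec.width))
    fy = np.fft.fftfreq(spec.height, d=spec.plate_scale_y / 60.0)
    fx = np.fft.fftfreq(spec.width, d=spec.plate_scale_x / 60.0)
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    envelope = np.zeros_like(fr)
    nz = fr > 0
    envelope[nz] = fr[nz] ** spec.slope
    shaped = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    shaped *= spec.contrast * 0.5 / shaped.std()
    return 0.5 + shaped


def _grating(spec: FrameSpec) -> np.ndarray:
    ydeg = np.arange(spec.height) * spec.plate_scale_y / 60.0
    xdeg = np.arange(spec.width) * spec.plate_scale_x / 60.0
    yy, xx = np.meshgrid(ydeg, xdeg, indexing="ij")
    theta = math.radians(spec.grating_orientation_deg)
    phase = 2.0 * math.pi * spec.grating_f0_cpd * (
        xx * math.cos(theta) + yy * math.sin(theta)
    )
    return 0.5 + 0.5 * spec.contrast * np.sin(phase)


def _edges(spec: FrameSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.full((spec.height, spec.width), 0.5)
    for _ in range(8):
        y0, y1 = np.sort(rng.integers(0, spec.height, 2))
        x0, x1 = np.sort(rng.integers(0, spec.width, 2))
        img[y0 : y1 + 1, x0 : x1 + 1] = rng.uniform(0.1, 0.9)
    return img


def gen_frames(spec: FrameSpec, n: int = 1) -> list[np.ndarray]:
    """Generate ``n`` 8-bit RGB frames, deterministic given ``spec.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    frames = []
    for _ in range(n):
        if spec.pattern == "noise1f":
            linear = _noise1f(spec, rng)
        elif spec.pattern == "grating":
            linear = _grating(spec)
        elif spec.pattern == "impulse":
            frame = np.zeros((spec.height, spec.width, 3), dtype=np.uint8)
            frame[spec.height // 2, spec.width // 2, :] = 255
            frames.append(frame)
            continue
        elif spec.pattern == "uniform":
            frame = np.full((spec.height, spec.width, 3), 128, dtype=np.uint8)
            frames.append(frame)
            continue
        elif spec.pattern == "edges":
            linear = _edges(spec, rng)
        else:
            raise ValueError(f"unknown pattern {spec.pattern!r}")
        frames.append(_encode(linear))
    return frames


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class EffectSpec:
    """True per-session change of each ocular component (post minus pre)."""

    d_acd_mean: float = 0.0
    d_acd_sd: float = 0.01
    d_lt_mean: float = 0.0
    d_lt_sd: float = 0.03
    d_vcd_mean: float = 0.0
    d_vcd_sd: float = 0.03
    d_cht_mean: float = 0.0
    d_cht_sd: float = 8.0


# Mean changes and spreads of the three study conditions (mm; ChT in um).
STUDY_EFFECTS: dict[str, EffectSpec] = {
    "reference": EffectSpec(
        d_lt_mean=-0.011, d_lt_sd=0.04, d_vcd_mean=-0.016, d_vcd_sd=0.03,
        d_cht_mean=0.899, d_cht_sd=7.65,
    ),
    "csm": EffectSpec(
        d_lt_mean=0.001, d_lt_sd=0.03, d_vcd_mean=-0.024, d_vcd_sd=0.04,
        d_cht_mean=3.67, d_cht_sd=10.93,
    ),
    "csh": EffectSpec(
        d_lt_mean=-0.033, d_lt_sd=0.03, d_vcd_mean=0.034, d_vcd_sd=0.03,
        d_cht_mean=1.21, d_cht_sd=10.95,
    ),
}

NULL_EFFECTS: dict[str, EffectSpec] = {
    c: EffectSpec() for c in ("reference", "csm", "csh")
}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort recipe.

    Baselines are drawn between subjects; replicate noise within a session;
    true condition effects per :class:`EffectSpec`.  ``assignment`` is
    ``"study"`` (8 subjects complete all three conditions, 7 reference+CSM,
    2 reference+CSH, matching a 17/15/10 unbalanced design) or ``"all"``
    (every subject completes every condition).
    """

    n_subjects: int = 17
    seed: int = 0
    assignment: Literal["study", "all"] = "study"
    effects: dict[str, EffectSpec] = field(
        default_factory=lambda: dict(STUDY_EFFECTS)
    )
    # between-subject baselines (mm / um)
    acd_mean: float = 3.65
    acd_sd: float = 0.25
    lt_mean: float = 3.50
    lt_sd: float = 0.20
    vcd_mean: float = 17.90
    vcd_sd: float = 0.90
    cht_mean: float = 236.26
    cht_sd: float = 69.88
    # within-subject noise
    replicate_sd_acd: float = 0.01
    replicate_sd_lt: float = 0.02
    replicate_sd_vcd: float = 0.02
    cht_visit_sd: float = 7.55
    cht_scan_sd: float = 5.0
    n_replicates: int = 5
    n_scans: int = 3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, value in asdict(self).items():
            if name.endswith("_sd") and value < 0:
                raise ValueError(f"{name} must be >= 0")

    def conditions_for(self, subject_index: int) -> list[str]:
        if self.assignment == "all":
            return ["reference", "csm", "csh"]
        # Proportions of the unbalanced study design: ~8/17 complete all
        # three, ~7/17 reference+CSM, ~2/17 reference+CSH.
        r = subject_index % 17
        scaled = (subject_index * 17) // self.n_subjects if self.n_subjects != 17 else r
        if scaled < 8:
            return ["reference", "csm", "csh"]
        if scaled < 15:
            return ["reference", "csm"]
        return ["reference", "csh"]


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a pre/post biometry cohort.

    Returns ``(biometry, cht, truth)``: a replicate-level biometer table
    (subject, condition, timepoint, replicate, ACD, LT, VCD, AL with
    AL = ACD + LT + VCD exactly), a scan-level choroidal-thickness table
    (subject, condition, timepoint, scan, subfoveal_um, widefield_um), and
    the full generating-parameter record.
    """
    rng = np.random.default_rng(spec.seed)
    bio_rows: list[dict] = []
    cht_rows: list[dict] = []
    for i in range(spec.n_subjects):
        subject = f"S{i + 1:04d}"
        base_acd = rng.normal(spec.acd_mean, spec.acd_sd)
        base_lt = rng.normal(spec.lt_mean, spec.lt_sd)
        base_vcd = rng.normal(spec.vcd_mean, spec.vcd_sd)
        base_cht = rng.normal(spec.cht_mean, spec.cht_sd)
        for condition in spec.conditions_for(i):
            eff = spec.effects[condition]
            true_change = {
                "ACD": rng.normal(eff.d_acd_mean, eff.d_acd_sd),
                "LT": rng.normal(eff.d_lt_mean, eff.d_lt_sd),
                "VCD": rng.normal(eff.d_vcd_mean, eff.d_vcd_sd),
            }
            cht_change = rng.normal(eff.d_cht_mean, eff.d_cht_sd)
            pre_true = {"ACD": base_acd, "LT": base_lt, "VCD": base_vcd}
            cht_pre_true = base_cht + rng.normal(0.0, spec.cht_visit_sd)
            for timepoint in ("pre", "post"):
                shift = true_change if timepoint == "post" else {k: 0.0 for k in pre_true}
                for rep in range(spec.n_replicates):
                    acd = pre_true["ACD"] + shift["ACD"] + rng.normal(0, spec.replicate_sd_acd)
                    lt = pre_true["LT"] + shift["LT"] + rng.normal(0, spec.replicate_sd_lt)
                    vcd = pre_true["VCD"] + shift["VCD"] + rng.normal(0, spec.replicate_sd_vcd)
                    bio_rows.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "timepoint": timepoint,
                            "replicate": rep + 1,
                            "ACD": acd,
                            "LT": lt,
                            "VCD": vcd,
                            "AL": acd + lt + vcd,
                        }
                    )
                cht_true = cht_pre_true + (cht_change if timepoint == "post" else 0.0)
                for scan in range(spec.n_scans):
                    cht_rows.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "timepoint": timepoint,
                            "scan": scan + 1,
                            "subfoveal_um": cht_true + rng.normal(0, spec.cht_scan_sd),
                            "widefield_um": cht_true + rng.normal(0, spec.cht_scan_sd),
                        }
                    )
    truth = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "effects"},
            "effects": {c: asdict(e) for c, e in spec.effects.items()},
        }
    }
    return pd.DataFrame(bio_rows), pd.DataFrame(cht_rows), truth


# ---------------------------------------------------------------------------
# choroid boundary traces


def gen_choroid_boundaries(
    thickness_field: Callable[[np.ndarray], np.ndarray],
    grader_noise_sd_um: float = 5.0,
    n_graders: int = 2,
    seed: int = 0,
    lateral_step_mm: float = 0.05,
    extent_mm: float = 4.6,
) -> tuple[dict[str, pd.DataFrame], ChoroidProfile]:
    """Simulate per-grader boundary traces around a known thickness field.

    ``thickness_field`` maps signed eccentricity (mm) to thickness (um) and
    must be positive over +/-4.5 mm.  The inner boundary is a smooth
    RPE-like curve; each grader's outer boundary adds spatially correlated
    (1-mm scale) noise plus white jitter, split so the two components sum
    to ``grader_noise_sd_um`` in quadrature.  Returns per-grader trace
    tables (lateral_mm, inner_um, outer_um) and the truth profile on the
    100-um analysis grid.
    """
    lateral = np.arange(-extent_mm, extent_mm + lateral_step_mm / 2, lateral_step_mm)
    thickness = np.asarray(thickness_field(lateral), dtype=float)
    if np.any(thickness <= 0):
        raise ValueError("thickness field must be positive across the scan")
    inner = 150.0 + 5.0 * lateral**2  # shallow RPE curvature, um
    rng = np.random.default_rng(seed)
    smooth_sd = 0.8 * grader_noise_sd_um
    jitter_sd = 0.6 * grader_noise_sd_um
    traces: dict[str, pd.DataFrame] = {}
    for g in range(n_graders):
        name = chr(ord("A") + g)
        smooth = gaussian_filter1d(
            rng.standard_normal(len(lateral)), sigma=1.0 / lateral_step_mm
        )
        if smooth.std() > 0:
            smooth *= smooth_sd / smooth.std()
        noise = smooth + rng.normal(0.0, jitter_sd, len(lateral))
        traces[name] = pd.DataFrame(
            {
                "lateral_mm": lateral,
                "inner_um": inner,
                "outer_um": inner + thickness + noise,
            }
        )
    truth = ChoroidProfile(
        thickness_um=np.asarray(thickness_field(ECCENTRICITY_GRID_MM), dtype=float)
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Monte-Carlo facility for the paired condition contrasts


def paired_test_rejection_mc(
    spec: CohortSpec,
    n_datasets: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rates of the pairwise condition contrasts over simulated
    cohorts.

    Simulates ``n_datasets`` cohorts with ``spec``'s variability structure
    (complete condition assignment), reduces replicates to session means,
    forms post-minus-pre VCD changes, and applies the same paired t-test
    per condition pair as :func:`biometry.condition_statistics`, with
    Bonferroni correction over the three contrasts.  Returns per-contrast
    uncorrected and corrected rejection rates and the family-wise rate.

    All draws are vectorized across datasets; with ``NULL_EFFECTS`` this
    measures the pipeline's type-I error.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    conditions = ("reference", "csm", "csh")
    n_s, n_r = spec.n_subjects, spec.n_replicates
    shape = (n_datasets, n_s, len(conditions))

    d_vcd = np.empty(shape)
    for j, cond in enumerate(conditions):
        eff = spec.effects[cond]
        true = rng.normal(eff.d_vcd_mean, eff.d_vcd_sd, (n_datasets, n_s))
        # replicate-mean noise at both timepoints
        rep_pre = rng.normal(0, spec.replicate_sd_vcd, (n_datasets, n_s, n_r)).mean(-1)
        rep_post = rng.normal(0, spec.replicate_sd_vcd, (n_datasets, n_s, n_r)).mean(-1)
        d_vcd[:, :, j] = true + rep_post - rep_pre

    pairs = [(0, 1), (0, 2), (1, 2)]
    names = ["reference_vs_csm", "reference_vs_csh", "csm_vs_csh"]
    p_vals = np.empty((n_datasets, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        res = sps.ttest_rel(d_vcd[:, :, a], d_vcd[:, :, b], axis=1)
        p_vals[:, k] = res.pvalue
    corrected = np.minimum(p_vals * len(pairs), 1.0)
    return {
        "n_datasets": n_datasets,
        "alpha": alpha,
        "per_contrast_uncorrected": dict(
            zip(names, (p_vals < alpha).mean(axis=0).tolist())
        ),
        "per_contrast_bonferroni": dict(
            zip(names, (corrected < alpha).mean(axis=0).tolist())
        ),
        "familywise_bonferroni": float((corrected < alpha).any(axis=1).mean()),
    }
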
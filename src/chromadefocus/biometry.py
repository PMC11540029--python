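"""Ocular biometry reduction and pre/post change statistics.

Covers the measurement pipeline of a pre/post stimulus-viewing study:

* replicate averaging of optical-biometer readings (axial length AL,
  vitreous chamber depth VCD, crystalline lens thickness LT, all mm);
* choroidal thickness (ChT, um) profiles on a fovea-centered 100-um grid
  spanning +/-4.5 mm of a 9-mm horizontal OCT scan, built from inner-RPE
  and choroid-sclera boundary traces;
* the multi-grader consensus rule (two-grader mean unless summaries differ
  by more than 15 um, in which case a third grader adjudicates);
* per-session post-minus-pre changes and condition comparisons: paired
  t-tests within condition, repeated-measures ANOVA across conditions with
  Bonferroni-corrected pairwise contrasts.

Sign conventions: eccentricity is signed with nasal negative and temporal
positive; changes are post minus pre; lengths are mm for biometer values
and um for ChT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ECCENTRICITY_GRID_MM",
    "BiometryReplicates",
    "ChoroidProfile",
    "GraderSet",
    "MergeResult",
    "SessionChange",
    "average_replicates",
    "profile_from_boundaries",
    "subfoveal_mean",
    "merge_graders",
    "session_change",
    "reduce_replicates",
    "compute_changes",
    "condition_statistics",
    "baseline_variability",
    "widefield_mean_change",
    "load_roster",
    "roster_summary",
]

# Fovea-centered lateral grid: 100-um steps across the central 9 mm.
ECCENTRICITY_GRID_MM = np.round(np.arange(-45, 46) * 0.1, 1)

PARAMS = ("AL", "VCD", "LT")
PHYSIO_BOUNDS = {"AL": (15.0, 35.0), "VCD": (10.0, 25.0), "LT": (2.0, 6.0)}


# ---------------------------------------------------------------------------
# replicate-level biometer data


@dataclass(frozen=True)
class BiometryReplicates:
    """Replicate (AL, VCD, LT) readings for one subject/condition/timepoint."""

    subject: str
    condition: str
    timepoint: str  # "pre" or "post"
    replicates: Sequence[tuple[float, float, float]]  # (AL, VCD, LT) mm

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        if len(self.replicates) == 0:
            raise ValueError("at least one replicate is required")


def _replicate_valid(al: float, vcd: float, lt: float) -> bool:
    if not (al > vcd > 0 and lt > 0):
        return False
    for name, value in zip(PARAMS, (al, vcd, lt)):
        lo, hi = PHYSIO_BOUNDS[name]
        if not (lo <= value <= hi):
            return False
    return True


def average_replicates(rep: BiometryReplicates) -> dict:
    """Arithmetic mean of valid replicates per parameter.

    Replicates violating physiological bounds or the AL > VCD ordering are
    excluded with a warning; zero valid replicates is an error.
    """
    valid = [r for r in rep.replicates if _replicate_valid(*r)]
    n_dropped = len(rep.replicates) - len(valid)
    if n_dropped:
        warnings.warn(
            f"{rep.subject}/{rep.condition}/{rep.timepoint}: excluded "
            f"{n_dropped} invalid replicate(s)",
            stacklevel=2,
        )
    if not valid:
        raise ValueError(
            f"no valid replicates for {rep.subject}/{rep.condition}/{rep.timepoint}"
        )
    arr = np.asarray(valid, dtype=float)
    means = arr.mean(axis=0)
    return {
        "AL": float(means[0]),
        "VCD": float(means[1]),
        "LT": float(means[2]),
        "n_replicates": len(valid),
    }


# ---------------------------------------------------------------------------
# choroid profiles


@dataclass(frozen=True)
class ChoroidProfile:
    """ChT (um) on the fovea-centered 100-um eccentricity grid (mm)."""

    thickness_um: np.ndarray
    eccentricity_mm: np.ndarray = field(
        default_factory=lambda: ECCENTRICITY_GRID_MM.copy()
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.thickness_um, dtype=float)
        e = np.asarray(self.eccentricity_mm, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("thickness and eccentricity grids must match, 1-D")
        if len(t) != len(ECCENTRICITY_GRID_MM):
            raise ValueError(
                f"expected {len(ECCENTRICITY_GRID_MM)} grid points, got {len(t)}"
            )
        if np.any(t <= 0) or np.any(t >= 1000):
            raise ValueError("thickness must lie in (0, 1000) um")
        object.__setattr__(self, "thickness_um", t)
        object.__setattr__(self, "eccentricity_mm", e)


def profile_from_boundaries(
    lateral_mm: np.ndarray,
    inner_um: np.ndarray,
    outer_um: np.ndarray,
    fovea_mm: float = 0.0,
) -> ChoroidProfile:
    """Thickness profile from inner-RPE and choroid-sclera boundary traces.

    Depth increases away from the vitreous, so the outer boundary must be
    deeper (larger) than the inner everywhere.  Thickness = outer - inner,
    linearly interpolated onto the 100-um grid centered on the fovea.
    """
    lateral = np.asarray(lateral_mm, dtype=float)
    inner = np.asarray(inner_um, dtype=float)
    outer = np.asarray(outer_um, dtype=float)
    if not (lateral.shape == inner.shape == outer.shape):
        raise ValueError("boundary traces must share their lateral grid")
    order = np.argsort(lateral)
    lateral, inner, outer = lateral[order], inner[order], outer[order]

    crossing = outer <= inner
    if np.any(crossing):
        where = lateral[crossing][0] - fovea_mm
        raise ValueError(
            f"outer boundary at or above inner boundary at eccentricity "
            f"{where:+.2f} mm"
        )
    rel = lateral - fovea_mm
    if rel.min() > ECCENTRICITY_GRID_MM[0] or rel.max() < ECCENTRICITY_GRID_MM[-1]:
        raise ValueError(
            f"traces cover [{rel.min():.2f}, {rel.max():.2f}] mm around the "
            "fovea; the full +/-4.5 mm extent is required"
        )
    inner_i = np.interp(ECCENTRICITY_GRID_MM, rel, inner)
    outer_i = np.interp(ECCENTRICITY_GRID_MM, rel, outer)
    return ChoroidProfile(thickness_um=outer_i - inner_i)


def subfoveal_mean(profile: ChoroidProfile) -> float:
    """Mean ChT over the central 1 mm (|eccentricity| <= 0.5 mm, 11 points)."""
    mask = np.abs(profile.eccentricity_mm) <= 0.5 + 1e-9
    return float(profile.thickness_um[mask].mean())


def widefield_mean(profile: ChoroidProfile) -> float:
    """Mean ChT across the full 9-mm grid (91 points)."""
    return float(profile.thickness_um.mean())


# ---------------------------------------------------------------------------
# grader consensus


@dataclass(frozen=True)
class GraderSet:
    """Profiles of one OCT image from two graders, plus an optional third."""

    grader_a: ChoroidProfile
    grader_b: ChoroidProfile
    grader_c: ChoroidProfile | None = None
    image_id: str = ""


@dataclass(frozen=True)
class MergeResult:
    consensus: ChoroidProfile | None
    status: str  # "two_grader_mean" | "three_grader_mean" | "needs_adjudication"
    audit: dict


def merge_graders(
    graders: GraderSet, tolerance_um: float = 15.0, pointwise: bool = False
) -> MergeResult:
    """Consensus profile under the 15-um adjudication rule.

    If the two graders' summaries (subfoveal means by default; maximum
    pointwise difference with ``pointwise=True``) agree within
    ``tolerance_um``, the consensus is their mean.  Otherwise adjudication
    is required: with a third grader supplied the consensus is the
    three-grader mean; without one, an explicit ``needs_adjudication``
    result is returned rather than a silent value.
    """
    a, b = graders.grader_a, graders.grader_b
    if pointwise:
        disagreement = float(np.max(np.abs(a.thickness_um - b.thickness_um)))
    else:
        disagreement = abs(subfoveal_mean(a) - subfoveal_mean(b))
    audit = {
        "image_id": graders.image_id,
        "disagreement_um": disagreement,
        "tolerance_um": tolerance_um,
        "rule": "pointwise" if pointwise else "subfoveal_summary",
    }
    if disagreement <= tolerance_um:
        consensus = ChoroidProfile((a.thickness_um + b.thickness_um) / 2.0)
        audit["n_graders"] = 2
        return MergeResult(consensus, "two_grader_mean", audit)
    if graders.grader_c is not None:
        consensus = ChoroidProfile(
            (a.thickness_um + b.thickness_um + graders.grader_c.thickness_um) / 3.0
        )
        audit["n_graders"] = 3
        return MergeResult(consensus, "three_grader_mean", audit)
    audit["n_graders"] = 2
    return MergeResult(None, "needs_adjudication", audit)


# ---------------------------------------------------------------------------
# session changes


@dataclass(frozen=True)
class SessionChange:
    """Post-minus-pre changes for one subject/condition session."""

    subject: str
    condition: str
    d_al_mm: float
    d_vcd_mm: float
    d_lt_mm: float
    d_cht_subfoveal_um: float | None = None
    d_cht_profile_um: np.ndarray | None = None


def session_change(pre: Mapping, post: Mapping) -> SessionChange:
    """Changes between matched pre and post session summaries.

    ``pre`` and ``post`` are mappings with keys subject, condition, AL,
    VCD, LT and optionally cht_subfoveal_um / cht_profile_um.
    """
    for key in ("subject", "condition"):
        if pre.get(key) != post.get(key):
            raise ValueError(
                f"mismatched {key}: pre={pre.get(key)!r}, post={post.get(key)!r}"
            )
    for key in PARAMS:
        if key not in pre or key not in post:
            raise ValueError(f"both timepoints must carry {key}")
    d_prof = None
    if pre.get("cht_profile_um") is not None and post.get("cht_profile_um") is not None:
        d_prof = np.asarray(post["cht_profile_um"], float) - np.asarray(
            pre["cht_profile_um"], float
        )
    d_sub = None
    if pre.get("cht_subfoveal_um") is not None and post.get("cht_subfoveal_um") is not None:
        d_sub = float(post["cht_subfoveal_um"]) - float(pre["cht_subfoveal_um"])
    return SessionChange(
        subject=pre["subject"],
        condition=pre["condition"],
        d_al_mm=float(post["AL"]) - float(pre["AL"]),
        d_vcd_mm=float(post["VCD"]) - float(pre["VCD"]),
        d_lt_mm=float(post["LT"]) - float(pre["LT"]),
        d_cht_subfoveal_um=d_sub,
        d_cht_profile_um=d_prof,
    )


def reduce_replicates(biometry: pd.DataFrame) -> pd.DataFrame:
    """Session summaries from a replicate-level biometry table.

    Expects columns subject, condition, timepoint, replicate, AL, VCD, LT;
    returns one row per subject/condition/timepoint with replicate means.
    """
    required = {"subject", "condition", "timepoint", "AL", "VCD", "LT"}
    missing = required - set(biometry.columns)
    if missing:
        raise ValueError(f"biometry table missing columns {sorted(missing)}")
    rows = []
    for (subj, cond, tp), grp in biometry.groupby(
        ["subject", "condition", "timepoint"], sort=True
    ):
        rep = BiometryReplicates(
            subject=str(subj),
            condition=str(cond),
            timepoint=str(tp),
            replicates=list(zip(grp["AL"], grp["VCD"], grp["LT"])),
        )
        means = average_replicates(rep)
        rows.append({"subject": subj, "condition": cond, "timepoint": tp, **means})
    return pd.DataFrame(rows)


def compute_changes(
    sessions: pd.DataFrame, cht: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Post-minus-pre change table from session summaries.

    ``sessions`` is the output of :func:`reduce_replicates`.  ``cht``
    optionally supplies scan-level ChT values (columns subject, condition,
    timepoint, scan, subfoveal_um and optionally widefield_um); scans are
    averaged per timepoint before differencing.
    """
    wide = sessions.pivot_table(
        index=["subject", "condition"], columns="timepoint", values=list(PARAMS)
    )
    rows = []
    for (subj, cond), row in wide.iterrows():
        if any(pd.isna(row[(p, tp)]) for p in PARAMS for tp in ("pre", "post")):
            continue
        rows.append(
            {
                "subject": subj,
                "condition": cond,
                "d_AL": row[("AL", "post")] - row[("AL", "pre")],
                "d_VCD": row[("VCD", "post")] - row[("VCD", "pre")],
                "d_LT": row[("LT", "post")] - row[("LT", "pre")],
            }
        )
    changes = pd.DataFrame(rows)
    if cht is not None and len(changes):
        value_cols = [
            c for c in ("subfoveal_um", "widefield_um") if c in cht.columns
        ]
        per_tp = (
            cht.groupby(["subject", "condition", "timepoint"])[value_cols]
            .mean()
            .reset_index()
        )
        for col, out in (
            ("subfoveal_um", "d_ChT_subfoveal"),
            ("widefield_um", "d_ChT_widefield"),
        ):
            if col not in value_cols:
                continue
            piv = per_tp.pivot_table(
                index=["subject", "condition"], columns="timepoint", values=col
            )
            delta = (piv["post"] - piv["pre"]).rename(out)
            changes = changes.merge(
                delta.reset_index(), on=["subject", "condition"], how="left"
            )
    return changes


# ---------------------------------------------------------------------------
# condition statistics


def _paired_table(changes: pd.DataFrame, parameter: str) -> pd.DataFrame:
    return changes.pivot_table(index="subject", columns="condition", values=parameter)


def condition_statistics(
    changes: pd.DataFrame,
    parameter: str = "d_VCD",
    alpha: float = 0.05,
) -> dict:
    """Summaries and tests of one change parameter across conditions.

    Returns per-condition mean +/- SD with a within-condition paired test of
    post vs. pre (one-sample t on the changes), a one-way repeated-measures
    ANOVA across conditions on complete cases, and Bonferroni-adjusted
    pairwise paired t-tests on all available subject pairs.  All tests are
    two-sided; every cell reports its n.
    """
    if parameter not in changes.columns:
        raise ValueError(f"no column {parameter!r} in changes table")
    conditions = sorted(changes["condition"].unique())
    if any(changes.groupby("condition")[parameter].count() < 2):
        raise ValueError("each compared condition needs at least 2 subjects")

    per_condition = {}
    for cond in conditions:
        vals = changes.loc[changes["condition"] == cond, parameter].dropna().to_numpy()
        t, p = sps.ttest_1samp(vals, 0.0)
        per_condition[cond] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(len(vals)),
            "t": float(t),
            "p": float(p),
        }

    wide = _paired_table(changes, parameter)
    complete = wide.dropna()
    rm_anova = None
    if len(conditions) >= 2 and len(complete) >= 2:
        import pingouin as pg

        long = complete.reset_index().melt(
            id_vars="subject", var_name="condition", value_name="change"
        )
        aov = pg.rm_anova(
            data=long, dv="change", within="condition", subject="subject", detailed=True
        )
        row = aov.loc[aov["Source"] == "condition"].iloc[0]
        rm_anova = {
            "F": float(row["F"]),
            "p": float(row["p_unc"]),
            "ddof1": float(row["DF"]),
            "n_complete": int(len(complete)),
        }

    pairs = [
        (a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]
    ]
    n_comparisons = max(len(pairs), 1)
    pairwise = {}
    for a, b in pairs:
        paired = wide[[a, b]].dropna()
        if len(paired) < 2:
            raise ValueError(
                f"insufficient pairing for contrast {a} vs {b} (n={len(paired)})"
            )
        t, p = sps.ttest_rel(paired[a], paired[b])
        pairwise[f"{a}_vs_{b}"] = {
            "mean_difference": float((paired[a] - paired[b]).mean()),
            "t": float(t),
            "p_uncorrected": float(p),
            "p_bonferroni": float(min(1.0, p * n_comparisons)),
            "significant": bool(p * n_comparisons < alpha),
            "n_pairs": int(len(paired)),
        }

    return {
        "parameter": parameter,
        "alpha": alpha,
        "per_condition": per_condition,
        "rm_anova": rm_anova,
        "pairwise": pairwise,
    }


def baseline_variability(baselines: pd.DataFrame, value: str = "subfoveal_um") -> dict:
    """Within- vs. between-subject spread of baseline subfoveal ChT.

    ``baselines`` has one row per subject visit (columns subject, visit,
    ``value``).  Returns per-subject across-visit mean and SD (flagged
    undefined for single-visit subjects), the cohort mean, and the
    between-subject SD of subject means.
    """
    if len(baselines) == 0:
        raise ValueError("empty baseline table")
    per_subject = {}
    for subj, grp in baselines.groupby("subject"):
        vals = grp[value].to_numpy(dtype=float)
        per_subject[subj] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else None,
            "n_visits": int(len(vals)),
        }
    subject_means = np.array([v["mean"] for v in per_subject.values()])
    within = [v["sd"] for v in per_subject.values() if v["sd"] is not None]
    return {
        "per_subject": per_subject,
        "cohort_mean": float(subject_means.mean()),
        "between_subject_sd": (
            float(subject_means.std(ddof=1)) if len(subject_means) >= 2 else None
        ),
        "mean_within_subject_sd": float(np.mean(within)) if within else None,
    }


def widefield_mean_change(
    changes: Sequence[SessionChange],
) -> pd.DataFrame:
    """Per subject/condition mean ChT change across the full 9-mm grid.

    Sessions without a full change profile are omitted with a warning.
    """
    rows = []
    for ch in changes:
        if ch.d_cht_profile_um is None:
            warnings.warn(
                f"{ch.subject}/{ch.condition}: no full-profile ChT change; omitted",
                stacklevel=2,
            )
            continue
        prof = np.asarray(ch.d_cht_profile_um, dtype=float)
        if len(prof) != len(ECCENTRICITY_GRID_MM):
            warnings.warn(
                f"{ch.subject}/{ch.condition}: incomplete profile; omitted",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "subject": ch.subject,
                "condition": ch.condition,
                "mean_d_ChT_um": float(prof.mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study roster


def load_roster(path: str | Path | None = None) -> pd.DataFrame:
    """Participant roster (one row per participant).

    Columns: subject, age_y, test_eye, cl_rx_D (contact-lens prescription,
    diopters), baseline_al_mm, and completed-condition flags reference /
    csm / csh (0/1).  Defaults to the packaged study roster.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "roster.csv"
    return pd.read_csv(path)


def roster_summary(roster: pd.DataFrame, scans_per_timepoint: int = 3) -> dict:
    """Counts derived from the roster.

    ``graded_images`` counts scans_per_timepoint scans x 2 timepoints x
    every completed subject-condition session.
    """
    flags = roster[["reference", "csm", "csh"]].astype(int)
    sessions = int(flags.to_numpy().sum())
    return {
        "n_participants": int(len(roster)),
        "n_completed_all_conditions": int((flags.sum(axis=1) == 3).sum()),
        "sessions_per_condition": {c: int(flags[c].sum()) for c in flags.columns},
        "n_sessions": sessions,
        "most_negative_cl_rx_D": float(roster["cl_rx_D"].min()),
        "graded_images": scans_per_timepoint * 2 * sessions,
    }
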
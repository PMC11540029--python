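"""Biometry reduction, choroid profiles, grader consensus, statistics."""

import numpy as np
import pandas as pd
import pytest

from chromadefocus.biometry import (
    ECCENTRICITY_GRID_MM,
    BiometryReplicates,
    ChoroidProfile,
    GraderSet,
    SessionChange,
    average_replicates,
    baseline_variability,
    compute_changes,
    condition_statistics,
    load_roster,
    merge_graders,
    profile_from_boundaries,
    reduce_replicates,
    roster_summary,
    session_change,
    subfoveal_mean,
    widefield_mean_change,
)


def flat_profile(value_um: float) -> ChoroidProfile:
    return ChoroidProfile(np.full(91, float(value_um)))


class TestAverageReplicates:
    def test_identical_replicates_return_value(self):
        rep = BiometryReplicates("S1", "reference", "pre", [(24.4, 17.8, 3.5)] * 5)
        out = average_replicates(rep)
        assert out["AL"] == 24.4 and out["n_replicates"] == 5

    def test_arithmetic_mean(self):
        rep = BiometryReplicates(
            "S1", "reference", "pre", [(24.40, 17.8, 3.5), (24.42, 17.8, 3.5)]
        )
        assert average_replicates(rep)["AL"] == pytest.approx(24.41)

    def test_invalid_replicate_excluded_with_warning(self):
        rep = BiometryReplicates(
            "S1", "csm", "post", [(24.4, 17.8, 3.5), (10.0, 17.8, 3.5)]
        )
        with pytest.warns(UserWarning, match="excluded"):
            out = average_replicates(rep)
        assert out["n_replicates"] == 1

    def test_no_valid_replicates_errors(self):
        rep = BiometryReplicates("S1", "csm", "post", [(10.0, 17.8, 3.5)])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no valid replicates"):
                average_replicates(rep)


class TestChoroidProfile:
    def test_flat_boundaries_yield_constant_profile(self):
        lateral = np.arange(-5.0, 5.01, 0.05)
        prof = profile_from_boundaries(
            lateral, np.full_like(lateral, 100.0), np.full_like(lateral, 350.0)
        )
        assert np.allclose(prof.thickness_um, 250.0)

    def test_gaussian_bump_recovered_within_interpolation_error(self):
        lateral = np.arange(-5.0, 5.01, 0.05)
        truth = 250.0 + 40.0 * np.exp(-(lateral**2) / 2.0)
        prof = profile_from_boundaries(
            lateral, np.full_like(lateral, 120.0), 120.0 + truth
        )
        expected = 250.0 + 40.0 * np.exp(-(ECCENTRICITY_GRID_MM**2) / 2.0)
        assert np.abs(prof.thickness_um - expected).max() < 1.0

    def test_offset_fovea_recenters_grid(self):
        lateral = np.arange(-4.0, 6.01, 0.05)
        ramp = 200.0 + 10.0 * lateral
        prof = profile_from_boundaries(
            lateral, np.zeros_like(lateral), ramp, fovea_mm=1.0
        )
        # at eccentricity 0 (lateral = 1.0 mm) thickness is 210
        assert prof.thickness_um[45] == pytest.approx(210.0, abs=1e-6)

    def test_insufficient_coverage_rejected(self):
        lateral = np.arange(-3.0, 3.01, 0.05)
        with pytest.raises(ValueError, match="extent"):
            profile_from_boundaries(
                lateral, np.zeros_like(lateral), np.full_like(lateral, 250.0)
            )

    def test_boundary_crossing_names_location(self):
        lateral = np.arange(-5.0, 5.01, 0.05)
        outer = np.full_like(lateral, 300.0)
        outer[lateral > 2.0] = -10.0
        with pytest.raises(ValueError, match=r"\+2"):
            profile_from_boundaries(lateral, np.zeros_like(lateral), outer)

    def test_subfoveal_mean_equals_bruteforce_central_mm(self, rng):
        values = rng.uniform(150, 400, 91)
        prof = ChoroidProfile(values)
        central = values[(np.abs(ECCENTRICITY_GRID_MM) <= 0.5)]
        assert len(central) == 11
        assert subfoveal_mean(prof) == pytest.approx(central.mean())


class TestMergeGraders:
    def test_two_grader_mean_within_tolerance(self):
        res = merge_graders(GraderSet(flat_profile(200), flat_profile(210)))
        assert res.status == "two_grader_mean"
        assert subfoveal_mean(res.consensus) == pytest.approx(205.0)

    def test_three_grader_mean_after_adjudication(self):
        res = merge_graders(
            GraderSet(flat_profile(200), flat_profile(220), flat_profile(210))
        )
        assert res.status == "three_grader_mean"
        assert subfoveal_mean(res.consensus) == pytest.approx(210.0)

    def test_needs_adjudication_without_third_grader(self):
        res = merge_graders(GraderSet(flat_profile(200), flat_profile(220)))
        assert res.status == "needs_adjudication"
        assert res.consensus is None
        assert res.audit["disagreement_um"] == pytest.approx(20.0)

    def test_symmetric_and_idempotent(self, rng):
        a = ChoroidProfile(rng.uniform(200, 210, 91))
        b = ChoroidProfile(rng.uniform(200, 210, 91))
        ab = merge_graders(GraderSet(a, b))
        ba = merge_graders(GraderSet(b, a))
        assert np.allclose(ab.consensus.thickness_um, ba.consensus.thickness_um)
        aa = merge_graders(GraderSet(a, a))
        assert np.allclose(aa.consensus.thickness_um, a.thickness_um)

    def test_pointwise_rule_stricter_than_summary(self):
        spike = np.full(91, 200.0)
        spike[80] = 230.0  # far from the fovea: summary barely moves
        a, b = flat_profile(200), ChoroidProfile(spike)
        assert merge_graders(GraderSet(a, b)).status == "two_grader_mean"
        assert (
            merge_graders(GraderSet(a, b), pointwise=True).status
            == "needs_adjudication"
        )


class TestSessionChange:
    def test_identical_sessions_have_zero_deltas(self):
        s = {"subject": "S1", "condition": "csm", "AL": 24.4, "VCD": 17.8, "LT": 3.5}
        ch = session_change(s, dict(s))
        assert ch.d_al_mm == ch.d_vcd_mm == ch.d_lt_mm == 0.0

    def test_post_minus_pre(self):
        pre = {"subject": "S1", "condition": "csh", "AL": 24.40, "VCD": 17.8, "LT": 3.5}
        post = {**pre, "AL": 24.43}
        assert session_change(pre, post).d_al_mm == pytest.approx(0.03)

    def test_mismatched_keys_rejected(self):
        pre = {"subject": "S1", "condition": "csh", "AL": 24.4, "VCD": 17.8, "LT": 3.5}
        post = {**pre, "subject": "S2"}
        with pytest.raises(ValueError, match="subject"):
            session_change(pre, post)

    def test_missing_parameter_rejected(self):
        pre = {"subject": "S1", "condition": "csh", "AL": 24.4, "VCD": 17.8, "LT": 3.5}
        post = {"subject": "S1", "condition": "csh", "AL": 24.4, "VCD": 17.8}
        with pytest.raises(ValueError, match="LT"):
            session_change(pre, post)


@pytest.fixture(scope="module")
def changes():
    from chromadefocus.synthdata import CohortSpec, gen_cohort

    bio, cht, _ = gen_cohort(CohortSpec(seed=11))
    return compute_changes(reduce_replicates(bio), cht)


class TestConditionStatistics:

    def test_summary_reports_all_cells_with_n(self, changes):
        stats = condition_statistics(changes, "d_VCD")
        assert set(stats["per_condition"]) == {"reference", "csm", "csh"}
        assert stats["per_condition"]["reference"]["n"] == 17
        assert stats["per_condition"]["csh"]["n"] == 10
        assert stats["rm_anova"]["n_complete"] == 8

    def test_identical_change_vectors_give_zero_contrast(self):
        rows = []
        for s in range(6):
            for c in ("reference", "csm"):
                rows.append({"subject": f"S{s}", "condition": c, "d_VCD": 0.01 * s})
        stats = condition_statistics(pd.DataFrame(rows), "d_VCD")
        contrast = stats["pairwise"]["csm_vs_reference"]
        assert contrast["mean_difference"] == 0.0

    def test_insufficient_pairing_is_a_named_error(self):
        rows = [
            {"subject": "S1", "condition": "reference", "d_VCD": 0.0},
            {"subject": "S2", "condition": "reference", "d_VCD": 0.01},
            {"subject": "S1", "condition": "csm", "d_VCD": 0.0},
            {"subject": "S3", "condition": "csm", "d_VCD": 0.02},
        ]
        with pytest.raises(ValueError, match="pairing"):
            condition_statistics(pd.DataFrame(rows), "d_VCD")

    def test_axial_length_bookkeeping_identity(self):
        from chromadefocus.synthdata import CohortSpec, gen_cohort

        bio, _, _ = gen_cohort(CohortSpec(seed=3))
        means = bio.groupby(["subject", "condition", "timepoint"])[
            ["ACD", "LT", "VCD", "AL"]
        ].mean()
        deltas = means.groupby(["subject", "condition"]).diff().dropna()
        assert np.allclose(
            deltas["AL"], deltas[["ACD", "LT", "VCD"]].sum(axis=1), atol=1e-12
        )


class TestBaselineVariability:
    def test_identical_baselines_have_zero_sd(self):
        df = pd.DataFrame(
            {"subject": ["S1"] * 3, "visit": [1, 2, 3], "subfoveal_um": [250.0] * 3}
        )
        out = baseline_variability(df)
        assert out["per_subject"]["S1"]["sd"] == 0.0

    def test_single_visit_sd_flagged_undefined(self):
        df = pd.DataFrame({"subject": ["S1"], "visit": [1], "subfoveal_um": [250.0]})
        out = baseline_variability(df)
        assert out["per_subject"]["S1"]["sd"] is None

    def test_variance_components_recovered(self, rng):
        between, within = 70.0, 8.0
        rows = []
        for s in range(200):
            mu = 236.0 + rng.normal(0, between)
            for v in range(3):
                rows.append(
                    {
                        "subject": f"S{s}",
                        "visit": v,
                        "subfoveal_um": mu + rng.normal(0, within),
                    }
                )
        out = baseline_variability(pd.DataFrame(rows))
        assert out["between_subject_sd"] == pytest.approx(between, rel=0.15)
        assert out["mean_within_subject_sd"] == pytest.approx(within, rel=0.15)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            baseline_variability(pd.DataFrame(columns=["subject", "subfoveal_um"]))


class TestWidefieldMeanChange:
    def test_uniform_change_recovered(self):
        ch = SessionChange("S1", "csh", 0, 0, 0, None, np.full(91, 10.0))
        out = widefield_mean_change([ch])
        assert out["mean_d_ChT_um"].iloc[0] == pytest.approx(10.0)

    def test_equals_bruteforce_grid_mean(self, rng):
        prof = rng.normal(0, 5, 91)
        ch = SessionChange("S1", "csm", 0, 0, 0, None, prof)
        out = widefield_mean_change([ch])
        assert out["mean_d_ChT_um"].iloc[0] == pytest.approx(prof.mean())

    def test_missing_profile_omitted_with_warning(self):
        changes = [
            SessionChange("S1", "csm", 0, 0, 0, None, np.full(91, 1.0)),
            SessionChange("S2", "csm", 0, 0, 0, None, None),
        ]
        with pytest.warns(UserWarning, match="omitted"):
            out = widefield_mean_change(changes)
        assert len(out) == 1


class TestRoster:
    def test_counts_and_sessions(self):
        summary = roster_summary(load_roster())
        assert summary["n_participants"] == 17
        assert summary["n_completed_all_conditions"] == 8
        assert summary["sessions_per_condition"] == {
            "reference": 17,
            "csm": 15,
            "csh": 10,
        }
        assert summary["graded_images"] == 3 * 2 * 42

    def test_most_negative_prescription(self):
        assert roster_summary(load_roster())["most_negative_cl_rx_D"] == -5.50
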
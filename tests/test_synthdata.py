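"""Synthetic generators: determinism, truth files, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from chromadefocus.biometry import (
    GraderSet,
    compute_changes,
    merge_graders,
    profile_from_boundaries,
    reduce_replicates,
    subfoveal_mean,
)
from chromadefocus.synthdata import (
    NULL_EFFECTS,
    CohortSpec,
    EffectSpec,
    FrameSpec,
    gen_choroid_boundaries,
    gen_cohort,
    gen_frames,
    paired_test_rejection_mc,
)


class TestGenFrames:
    def test_impulse_is_single_white_pixel(self):
        frame = gen_frames(FrameSpec(width=65, height=65, pattern="impulse"), 1)[0]
        assert frame[32, 32, 0] == 255
        assert frame.sum() == 255 * 3

    def test_uniform_is_constant(self):
        frame = gen_frames(FrameSpec(pattern="uniform", width=32, height=32), 1)[0]
        assert np.all(frame == 128)

    def test_seed_determinism(self):
        a = gen_frames(FrameSpec(seed=42), 3)
        b = gen_frames(FrameSpec(seed=42), 3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = gen_frames(FrameSpec(seed=43), 1)[0]
        assert not np.array_equal(a[0], c)

    def test_noise1f_slope_matches_spec(self):
        from chromadefocus.spectral import aggregate_spectra, spectral_slope

        for slope in (-0.8, -1.2):
            frames = gen_frames(
                FrameSpec(width=256, height=256, slope=slope, seed=1), 10
            )
            linear = [
                np.repeat((f[:, :, :1].astype(float) / 255.0) ** 2.2, 3, axis=2)
                for f in frames
            ]
            s = aggregate_spectra(
                linear, 0, 60 * 28.5 / 1920, 60 * 17 / 1080
            )
            assert spectral_slope(s) == pytest.approx(slope, abs=0.1)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            FrameSpec(slope=0.5)


class TestGenCohort:
    def test_zero_sds_and_null_effects_make_post_equal_pre(self):
        spec = CohortSpec(
            n_subjects=4,
            seed=0,
            assignment="all",
            effects={
                c: EffectSpec(d_acd_sd=0, d_lt_sd=0, d_vcd_sd=0, d_cht_sd=0)
                for c in ("reference", "csm", "csh")
            },
            acd_sd=0,
            lt_sd=0,
            vcd_sd=0,
            cht_sd=0,
            replicate_sd_acd=0,
            replicate_sd_lt=0,
            replicate_sd_vcd=0,
            cht_visit_sd=0,
            cht_scan_sd=0,
        )
        bio, cht, _ = gen_cohort(spec)
        wide = bio.pivot_table(
            index=["subject", "condition", "replicate"],
            columns="timepoint",
            values="AL",
        )
        assert np.allclose(wide["pre"], wide["post"])
        assert cht["subfoveal_um"].nunique() == 1

    def test_seed_determinism(self):
        a, acht, _ = gen_cohort(CohortSpec(seed=9))
        b, bcht, _ = gen_cohort(CohortSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(acht, bcht)

    def test_study_assignment_is_unbalanced_17_15_10(self):
        bio, _, _ = gen_cohort(CohortSpec(seed=1))
        counts = (
            bio.groupby("condition")["subject"].nunique().to_dict()
        )
        assert counts == {"reference": 17, "csm": 15, "csh": 10}

    def test_truth_records_generating_parameters(self):
        spec = CohortSpec(seed=5)
        _, _, truth = gen_cohort(spec)
        assert truth["spec"]["seed"] == 5
        assert truth["spec"]["effects"]["csh"]["d_vcd_mean"] == pytest.approx(0.034)

    def test_effect_recovery_within_three_se(self):
        spec = CohortSpec(n_subjects=400, seed=21, assignment="all")
        bio, _, truth = gen_cohort(spec)
        changes = compute_changes(reduce_replicates(bio))
        for cond in ("csm", "csh"):
            got = changes.loc[changes.condition == cond, "d_VCD"]
            se = got.std(ddof=1) / np.sqrt(len(got))
            truth_mean = truth["spec"]["effects"][cond]["d_vcd_mean"]
            assert abs(got.mean() - truth_mean) < 3 * se


class TestGenChoroidBoundaries:
    @staticmethod
    def bump(ecc):
        return 250.0 + 40.0 * np.exp(-np.asarray(ecc, float) ** 2 / 2.0)

    def test_zero_noise_reproduces_field_exactly(self):
        traces, truth = gen_choroid_boundaries(
            lambda e: np.full(np.asarray(e).shape, 250.0), 0.0, 2, seed=0
        )
        df = traces["A"]
        prof = profile_from_boundaries(
            df.lateral_mm.values, df.inner_um.values, df.outer_um.values
        )
        assert np.allclose(prof.thickness_um, 250.0, atol=1e-9)
        assert np.allclose(truth.thickness_um, 250.0)

    def test_recovered_profile_rmse_bounded_by_noise(self):
        sd = 5.0
        traces, truth = gen_choroid_boundaries(self.bump, sd, 2, seed=3)
        errors = []
        for df in traces.values():
            prof = profile_from_boundaries(
                df.lateral_mm.values, df.inner_um.values, df.outer_um.values
            )
            errors.append(prof.thickness_um - truth.thickness_um)
        rmse = np.sqrt(np.mean(np.square(errors)))
        assert rmse < 2.0 * sd

    def test_large_noise_triggers_adjudication_flag(self):
        traces, _ = gen_choroid_boundaries(self.bump, 60.0, 2, seed=8)
        profs = [
            profile_from_boundaries(
                df.lateral_mm.values, df.inner_um.values, df.outer_um.values
            )
            for df in traces.values()
        ]
        assert abs(subfoveal_mean(profs[0]) - subfoveal_mean(profs[1])) > 15.0
        res = merge_graders(GraderSet(profs[0], profs[1]))
        assert res.status == "needs_adjudication"

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            gen_choroid_boundaries(lambda e: np.asarray(e, float) * 0.0, 5.0, 2, seed=0)


class TestPairedTestMonteCarlo:
    def test_pvalues_match_condition_statistics_pipeline(self):
        # Dual route: the vectorized Monte Carlo applies exactly the paired
        # t-test that condition_statistics reports per contrast.
        from scipy import stats as sps

        from chromadefocus.biometry import condition_statistics

        spec = CohortSpec(seed=77, assignment="all", effects=dict(NULL_EFFECTS))
        bio, _, _ = gen_cohort(spec)
        changes = compute_changes(reduce_replicates(bio))
        stats = condition_statistics(changes, "d_VCD")
        wide = changes.pivot_table(index="subject", columns="condition", values="d_VCD")
        t, p = sps.ttest_rel(wide["csm"], wide["csh"])
        assert stats["pairwise"]["csh_vs_csm"]["p_uncorrected"] == pytest.approx(p)

    def test_null_rejection_rate_near_alpha(self):
        spec = CohortSpec(seed=1, effects=dict(NULL_EFFECTS))
        out = paired_test_rejection_mc(spec, n_datasets=2000, seed=13)
        for rate in out["per_contrast_uncorrected"].values():
            # 99.9% binomial band around 0.05 at n=2000
            assert abs(rate - 0.05) < 3.3 * np.sqrt(0.05 * 0.95 / 2000)
        assert out["familywise_bonferroni"] <= 0.07
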
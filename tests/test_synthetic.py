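"""Synthetic-study generator: sampling targets, forward model, determinism."""

import numpy as np
import pytest

from cobrairs.deconvolution import PATTERN_COLS, deconvolve_lanes
from cobrairs.densitometry import EffectiveLengthTable
from cobrairs.synthetic import (
    CohortSpec,
    GelNoiseModel,
    StudyCohort,
    StudyConfig,
    frequencies_to_lane,
    generate_study,
    sample_pattern_frequencies,
)

TABLE3_NEUT_CONTROL = CohortSpec(
    group="control", n=15,
    means=(14.25, 32.39, 24.87, 28.49), sds=(3.68, 1.81, 1.40, 1.03),
)


class TestCohortSpec:
    def test_means_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to ~100"):
            CohortSpec("g", 5, (10, 10, 10, 10), (1, 1, 1, 1))

    def test_all_zero_means_infeasible(self):
        with pytest.raises(ValueError, match="nonnegative|zero"):
            CohortSpec("g", 5, (0, 0, 0, 0), (1, 1, 1, 1))

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CohortSpec("g", 1, (25, 25, 25, 25), (1, 1, 1, 1))


class TestSamplePatternFrequencies:
    def test_zero_sd_returns_renormalized_means(self):
        spec = CohortSpec("g", 4, (14.25, 32.39, 24.87, 28.49), (0, 0, 0, 0))
        f = sample_pattern_frequencies(spec, seed=0)
        expected = 100 * np.array(spec.means) / sum(spec.means)
        assert f == pytest.approx(np.tile(expected, (4, 1)))

    def test_outputs_on_simplex(self):
        f = sample_pattern_frequencies(TABLE3_NEUT_CONTROL, seed=1)
        assert f.shape == (15, 4)
        assert (f >= 0).all()
        assert f.sum(axis=1) == pytest.approx(np.full(15, 100.0))

    def test_reproducible_under_seed(self):
        f1 = sample_pattern_frequencies(TABLE3_NEUT_CONTROL, seed=99)
        f2 = sample_pattern_frequencies(TABLE3_NEUT_CONTROL, seed=99)
        assert np.array_equal(f1, f2)

    def test_monte_carlo_moments_near_targets(self):
        """At n = 10^4 the empirical means land within 0.2 points and the
        SDs within 15% of the spec targets (variance compensation undoes
        the renormalization cross-talk when the targets are attainable)."""
        spec = CohortSpec(
            "g", 10_000,
            means=(13.72, 31.25, 24.46, 30.58), sds=(1.21, 0.93, 0.76, 1.13),
        )
        f = sample_pattern_frequencies(spec, seed=7)
        assert f.mean(axis=0) == pytest.approx(spec.means, abs=0.2)
        assert f.std(axis=0, ddof=1) == pytest.approx(spec.sds, rel=0.15)

    def test_heterogeneous_sds_hit_targets_or_floor(self):
        """When one pattern's SD target lies below the cross-talk floor of
        the others (neutrophil-control-like spec), the attainable patterns
        still match within 15% and the floored one never undershoots."""
        spec = CohortSpec("g", 10_000, TABLE3_NEUT_CONTROL.means,
                          TABLE3_NEUT_CONTROL.sds)
        f = sample_pattern_frequencies(spec, seed=7)
        sd = f.std(axis=0, ddof=1)
        assert f.mean(axis=0) == pytest.approx(spec.means, abs=0.2)
        assert sd[:3] == pytest.approx(spec.sds[:3], rel=0.15)
        assert spec.sds[3] <= sd[3] <= 1.5 * spec.sds[3]


class TestFrequenciesToLane:
    def test_pure_uncut_alu_band(self, as_printed):
        lane = frequencies_to_lane((0.0, 0.0, 0.0, 100.0), "ALU", as_printed, scale=2.0)
        assert lane.bands == pytest.approx({133: 100 * 131 * 2.0})

    def test_scale_cancels_downstream(self, as_printed):
        f = (14.25, 32.39, 24.87, 28.49)
        lanes = [
            frequencies_to_lane(f, "ALU", as_printed, scale=s, sample_id=f"s{s}")
            for s in (1.0, 2.0)
        ]
        assert lanes[1].bands == pytest.approx(
            {k: 2 * v for k, v in lanes[0].bands.items()}
        )
        freq = deconvolve_lanes(lanes, as_printed)
        assert np.allclose(
            freq.loc[0, PATTERN_COLS].to_numpy(dtype=float),
            freq.loc[1, PATTERN_COLS].to_numpy(dtype=float),
        )

    def test_line1_18bp_band_hidden_by_default(self, as_printed):
        f = (60.0, 20.0, 10.0, 10.0)
        hidden = frequencies_to_lane(f, "LINE1", as_printed)
        shown = frequencies_to_lane(f, "LINE1", as_printed, visible_18=True)
        assert 18 not in hidden.bands
        assert 18 in shown.bands

    def test_off_simplex_vector_rejected(self, as_printed):
        with pytest.raises(ValueError, match="summing to 100"):
            frequencies_to_lane((50.0, 10.0, 10.0, 10.0), "ALU", as_printed)


class TestGenerateStudy:
    def test_deterministic_per_seed(self):
        cfg = StudyConfig.default()
        s1 = generate_study(cfg, seed=5)
        s2 = generate_study(cfg, seed=5)
        assert s1.lanes == s2.lanes
        assert s1.truth.equals(s2.truth)
        s3 = generate_study(cfg, seed=6)
        assert s1.lanes != s3.lanes

    def test_default_design_shape(self):
        study = generate_study(StudyConfig.default(), seed=0)
        # (15 + 12 + 17) samples x 2 cell types x 2 assays
        assert len(study.lanes) == 44 * 4
        assert len(study.control_lanes) == 3 * 3 * 2  # lines x batches x assays
        assert set(study.truth["group"]) == {"control", "active", "inactive"}
        assert study.truth["batch"].nunique() == 3

    def test_truth_matches_deconvolution_at_sigma_zero(self, as_printed):
        cfg = StudyConfig(
            cohorts=(StudyCohort("ALU", "PBMC", TABLE3_NEUT_CONTROL),
                     StudyCohort("LINE1", "PBMC", TABLE3_NEUT_CONTROL)),
            noise=GelNoiseModel(sigma=0.0),
        )
        study = generate_study(cfg, seed=3)
        freq = deconvolve_lanes(study.lanes, as_printed)
        merged = freq.merge(
            study.truth, on=["sample_id", "assay", "cell_type", "group", "batch"],
            suffixes=("", "_truth"),
        )
        assert len(merged) == len(freq)
        for col in PATTERN_COLS:
            assert merged[col].to_numpy() == pytest.approx(
                merged[f"{col}_truth"].to_numpy(), abs=1e-9
            )

    def test_parameter_recovery_under_noise(self, as_printed):
        """With sigma = 0.05 and 50 samples per group, deconvolved group
        means stay within 0.5 points of the simulated ground truth."""
        spec = CohortSpec("control", 50, TABLE3_NEUT_CONTROL.means, TABLE3_NEUT_CONTROL.sds)
        cfg = StudyConfig(
            cohorts=(StudyCohort("ALU", "NEUTROPHIL", spec),),
            noise=GelNoiseModel(sigma=0.05),
        )
        study = generate_study(cfg, seed=11)
        freq = deconvolve_lanes(study.lanes, as_printed)
        got = freq[PATTERN_COLS].mean().to_numpy()
        want = study.truth[PATTERN_COLS].mean().to_numpy()
        assert got == pytest.approx(want, abs=0.5)

    def test_batch_effect_removed_by_normalization(self, as_printed):
        """Injected per-batch offsets visible in the control lanes are
        removed: between-batch variance of control-line frequencies drops
        by >= 90% after normalization."""
        from cobrairs.deconvolution import interassay_normalize

        offsets = {
            "b1": (2.0, -2.0, 1.0, -1.0),
            "b2": (-1.5, 1.5, -1.0, 1.0),
            "b3": (0.0, 0.0, 0.0, 0.0),
        }
        spec = CohortSpec("control", 30, TABLE3_NEUT_CONTROL.means, TABLE3_NEUT_CONTROL.sds)
        cfg = StudyConfig(
            cohorts=(StudyCohort("ALU", "NEUTROPHIL", spec),),
            noise=GelNoiseModel(sigma=0.0, batch_offset=offsets),
        )
        study = generate_study(cfg, seed=2)
        ctrl_freq = deconvolve_lanes(study.control_lanes, as_printed)
        ctrl_freq["control_line"] = [
            lane.sample_id.rsplit("_", 1)[0] for lane in study.control_lanes
        ]
        before = (
            ctrl_freq.groupby("control_line")[PATTERN_COLS].var().to_numpy().sum()
        )
        normalized = interassay_normalize(ctrl_freq, ctrl_freq)
        normalized["control_line"] = ctrl_freq["control_line"]
        after = (
            normalized.groupby("control_line")[PATTERN_COLS].var().to_numpy().sum()
        )
        assert after <= 0.1 * before


class TestYamlConfig:
    def test_round_trip_through_yaml(self, tmp_path):
        import yaml

        doc = {
            "cohorts": [
                {"assay": "ALU", "cell_type": "PBMC", "group": "control",
                 "n": 5, "means": [14.25, 32.39, 24.87, 28.49],
                 "sds": [1, 1, 1, 1]},
            ],
            "noise": {"sigma": 0.1, "batch_scale": {"b1": 1.2}},
            "batches": ["b1", "b2"],
        }
        path = tmp_path / "study.yaml"
        path.write_text(yaml.safe_dump(doc))
        cfg = StudyConfig.from_yaml(path)
        assert cfg.noise.sigma == 0.1
        assert cfg.batches == ("b1", "b2")
        assert cfg.cohorts[0].spec.n == 5
        generate_study(cfg, seed=1)  # usable end to end
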
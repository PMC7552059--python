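import numpy as np
import pandas as pd
import pytest

from fixtures_qc import COMPLIANT, FORMULAS, VIOLATING, build_fixture
from vdomics.qc import (
    align_peaks,
    blank_filter,
    flag_replicate_outliers,
    min_occurrence_filter,
    normalize,
    raise_detection_limit,
    run_qc,
)


@pytest.fixture(scope="module")
def planted():
    assignments, metas = build_fixture()
    return align_peaks(assignments, metas)


class TestAlign:
    def test_formula_keyed_features(self, planted):
        for name, text in FORMULAS.items():
            assert text in planted.intensity.columns, name
        assert set(planted.formula_features) == set(FORMULAS.values())

    def test_unassigned_peaks_get_mz_keys(self, planted):
        mz_keys = [c for c in planted.intensity.columns if c.startswith("mz_")]
        # one floor peak per spectrum, all at distinct m/z
        assert len(mz_keys) == 16

    def test_min_intensity_recorded(self, planted):
        assert planted.min_intensity["s1"] == 100.0
        assert planted.min_intensity["b1"] == 100.0

    def test_sub_threshold_and_low_snr_excluded(self, small_assignments, small_experiment, rules):
        _, metas = small_experiment
        m = align_peaks(small_assignments, metas, min_snr=rules.min_snr)
        assert (m.snr.to_numpy()[m.snr.to_numpy() > 0] >= rules.min_snr).all()

    def test_within_tolerance_unassigned_peaks_cluster(self):
        from vdomics.assignment import Assignment
        from vdomics.datamodel import Peak, SampleMeta

        metas = [SampleMeta(s, "surface", "treatment", 0, i + 1) for i, s in enumerate(["x", "y"])]
        asg = {
            "x": [Assignment(Peak(400.0000000, 10.0, 5.0), None, None, "no_candidate")],
            "y": [Assignment(Peak(400.0000800, 20.0, 5.0), None, None, "no_candidate")],
        }
        m = align_peaks(asg, metas, tol_ppm=0.5)
        assert m.n_features() == 1
        asg["y"] = [Assignment(Peak(400.01, 20.0, 5.0), None, None, "no_candidate")]
        assert align_peaks(asg, metas, tol_ppm=0.5).n_features() == 2


class TestFilters:
    def test_raised_limit_removes_exactly_sub_limit_entries(self, planted):
        out = raise_detection_limit(planted)
        assert FORMULAS["C_lim"] not in out.intensity.columns
        assert FORMULAS["E_ok"] in out.intensity.columns
        # every spectrum's original minimum peak is gone
        for s in planted.intensity.index:
            row = out.intensity.loc[s]
            assert (row[row > 0] >= 1.05 * planted.min_intensity[s] - 1e-9).all()

    def test_min_occurrence_counts_study_samples_only(self, planted):
        out = min_occurrence_filter(raise_detection_limit(planted))
        assert FORMULAS["B_occ"] not in out.intensity.columns
        # blank-only floor peaks are gone too
        assert not any(c.startswith("mz_") for c in out.intensity.columns)

    def test_blank_filter_both_rules(self, planted):
        out = blank_filter(min_occurrence_filter(raise_detection_limit(planted)))
        cols = set(out.intensity.columns)
        assert FORMULAS["G_snr"] not in cols  # 20x S/N rule
        assert FORMULAS["H_maj"] not in cols  # 7-of-10 rule
        assert FORMULAS["I_ok"] in cols
        assert out.blank_samples == []

    def test_planted_violations_fully_resolved(self, planted):
        out = blank_filter(min_occurrence_filter(raise_detection_limit(planted)))
        cols = set(out.intensity.columns)
        assert cols == {FORMULAS[k] for k in COMPLIANT}
        assert not cols & {FORMULAS[k] for k in VIOLATING}

    def test_filters_idempotent(self, planted):
        a = raise_detection_limit(planted)
        assert raise_detection_limit(a).intensity.equals(a.intensity)
        b = min_occurrence_filter(a)
        assert min_occurrence_filter(b).intensity.equals(b.intensity)
        c = blank_filter(b)
        assert blank_filter(c).intensity.equals(c.intensity)

    def test_filters_only_shrink(self, planted):
        a = raise_detection_limit(planted)
        b = min_occurrence_filter(a)
        c = blank_filter(b)
        assert a.n_features() <= planted.n_features()
        assert b.n_features() <= a.n_features()
        assert c.n_features() <= b.n_features()
        assert set(c.intensity.columns) <= set(planted.intensity.columns)

    def test_limit_factor_below_one_rejected(self, planted):
        with pytest.raises(ValueError):
            raise_detection_limit(planted, factor=0.9)


class TestOutliers:
    def test_manual_passthrough_and_unknown_id(self, planted):
        assert flag_replicate_outliers(planted, manual_ids=["s1"]) == ["s1"]
        with pytest.raises(ValueError, match="nope"):
            flag_replicate_outliers(planted, manual_ids=["nope"])

    def test_all_replicates_of_condition_rejected(self, planted):
        with pytest.raises(ValueError, match="all replicates"):
            flag_replicate_outliers(planted, manual_ids=["s1", "s2", "s3"])

    def test_distance_mode_flags_divergent_replicate(self, planted):
        m = blank_filter(min_occurrence_filter(raise_detection_limit(planted)))
        # undisturbed replicates are near-identical: nothing flagged
        assert flag_replicate_outliers(m, method="distance", threshold=0.3) == []
        skew = m.intensity.copy()
        cols = list(skew.columns)
        skew.loc["s1", cols[0]] = 1e6  # s1 now dominated by one feature
        from dataclasses import replace

        m2 = replace(m, intensity=skew)
        # the group center includes s1 itself, which caps the attainable
        # dissimilarity for a 3-replicate group near 1/3
        assert flag_replicate_outliers(m2, method="distance", threshold=0.3) == ["s1"]

    def test_unknown_method(self, planted):
        with pytest.raises(ValueError):
            flag_replicate_outliers(planted, method="magic")


class TestNormalize:
    def test_rows_sum_to_one_over_assigned(self, planted):
        m = blank_filter(min_occurrence_filter(raise_detection_limit(planted)))
        t = normalize(m)
        assert t.normalized
        np.testing.assert_allclose(t.values.sum(axis=1), 1.0)
        # s1: A=1000, E=106, I=1000
        assert t.values.loc["s1", FORMULAS["A_ok"]] == pytest.approx(1000 / 2106)

    def test_excluded_outliers_dropped(self, planted):
        m = blank_filter(min_occurrence_filter(raise_detection_limit(planted)))
        t = normalize(m, exclude=["s1"])
        assert "s1" not in t.values.index

    def test_all_peaks_denominator(self, planted):
        # before the raised limit the unassigned floor peaks are still present
        t = normalize(planted, total="all_peaks")
        assert not t.normalized
        assert (t.values.sum(axis=1) < 1.0 - 1e-9).all()

    def test_unknown_total_rejected(self, planted):
        with pytest.raises(ValueError):
            normalize(planted, total="everything")


class TestRunQc:
    def test_pipeline_on_planted_fixture(self):
        assignments, metas = build_fixture()
        t = run_qc(assignments, metas)
        assert set(t.values.columns) == {FORMULAS[k] for k in COMPLIANT}
        assert list(t.values.index) == [f"s{i}" for i in range(1, 7)]
        np.testing.assert_allclose(t.values.sum(axis=1), 1.0)

    def test_pipeline_on_simulated_data(self, small_table):
        vals = small_table.values
        assert vals.shape[0] == 48
        np.testing.assert_allclose(vals.sum(axis=1), 1.0)
        assert (vals.to_numpy() >= 0).all()
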
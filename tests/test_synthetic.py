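import numpy as np
import pandas as pd
import pytest

from vdomics.assignment import monoisotopic_mass, neutral_mass_to_mz
from vdomics.diversity import pielou
from vdomics.synthetic import (
    ENV_PARAMETERS,
    SimulationConfig,
    generate_env_table,
    generate_formula_library,
    generate_otu_table,
    simulate_experiment,
)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, vdom_removal_prob=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, noise_snr_below_threshold_frac=-0.1)

    def test_lysis_depth_must_exist(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, lysis_depth="abyssal")

    def test_detection_prob_monotone(self):
        cfg = SimulationConfig(seed=1)
        x = np.array([10.0, 100.0, 1000.0, 1e5])
        p = cfg.detection_prob(x)
        assert (np.diff(p) >= 0).all()
        assert p[0] < 0.01 and p[-1] > 0.99


class TestLibraryGeneration:
    def test_deterministic_under_seed(self, small_config):
        a = generate_formula_library(small_config)
        b = generate_formula_library(small_config)
        assert a.library == b.library
        assert a.vdom == b.vdom
        assert a.removed_set == b.removed_set
        assert a.blank_shared == b.blank_shared

    def test_seed_changes_output(self, small_config, small_truth):
        from dataclasses import replace

        other = generate_formula_library(replace(small_config, seed=small_config.seed + 1))
        assert set(other.vdom) != set(small_truth.vdom)

    def test_set_sizes_and_disjointness(self, small_config, small_truth):
        assert len(small_truth.library) == small_config.n_library
        assert len(small_truth.vdom) == small_config.n_vdom
        assert len(small_truth.blank_unique) == small_config.n_blank_unique
        assert not set(small_truth.library) & set(small_truth.vdom)
        assert not set(small_truth.vdom) & set(small_truth.blank_unique)
        assert small_truth.blank_shared <= set(small_truth.library)
        n_removed = round(small_config.vdom_removal_prob * small_config.n_vdom)
        assert len(small_truth.removed_set) == n_removed
        assert small_truth.removed_set <= small_truth.vdom_set

    def test_heteroatom_targets_exact(self, small_config, small_truth):
        vdom = list(small_truth.vdom)
        n = len(vdom)
        tn, ts, tp = small_config.vdom_heteroatom_targets
        assert sum(f.n > 0 for f in vdom) == round(tn * n)
        assert sum(f.s > 0 for f in vdom) == round(ts * n)
        assert sum(f.p > 0 for f in vdom) == round(tp * n)

    def test_formulas_inside_realistic_band(self, small_config, small_truth):
        for f in list(small_truth.library)[:200]:
            hc, oc = f.h / f.c, f.o / f.c
            assert small_config.hc_band[0] <= hc <= small_config.hc_band[1]
            assert small_config.oc_band[0] <= oc <= small_config.oc_band[1]
            m = monoisotopic_mass(f)
            assert small_config.mass_range[0] <= m <= small_config.mass_range[1]

    def test_truth_ledger_frame(self, small_config, small_truth):
        df = small_truth.to_frame()
        assert set(df["role"]) == {
            "library", "vdom", "blank_shared_contaminant", "blank_unique_contaminant"
        }
        n_total = (small_config.n_library + small_config.n_vdom
                   + small_config.n_blank_unique)
        assert len(df) == n_total
        assert df.loc[df["role"] == "vdom", "removed_at_final_day"].sum() == len(
            small_truth.removed_set
        )


class TestSimulateExperiment:
    def test_design_arithmetic(self, small_config, small_experiment):
        spectra, metas = small_experiment
        n_study = (len(small_config.depths) * 2 * len(small_config.days)
                   * small_config.replicates)
        assert len(spectra) == n_study + small_config.n_blanks == 58
        assert sum(m.is_blank for m in metas) == small_config.n_blanks
        ids = {sp.sample_id for sp in spectra}
        assert len(ids) == len(spectra)
        assert "subsurface_treatment_d06_r1" in ids

    def test_bitwise_determinism(self, small_config, small_truth, small_experiment):
        spectra2, _ = simulate_experiment(small_truth)
        first, again = small_experiment[0][0], spectra2[0]
        assert [p.mz for p in first.peaks] == [p.mz for p in again.peaks]
        assert [p.intensity for p in first.peaks] == [p.intensity for p in again.peaks]

    def test_zero_jitter_gives_exact_masses(self):
        from dataclasses import replace

        cfg = SimulationConfig(seed=5, n_library=80, n_vdom=20, n_noise_peaks=0,
                               mass_jitter_ppm_sd=0.0)
        truth = generate_formula_library(cfg)
        spectra, _ = simulate_experiment(truth)
        exact = {
            round(neutral_mass_to_mz(monoisotopic_mass(f)), 9)
            for f in (set(truth.library) | set(truth.vdom) | set(truth.blank_unique))
        }
        sp = spectra[0]
        assert sp.peaks, "empty spectrum"
        for p in sp.peaks:
            assert round(p.mz, 9) in exact

    def test_removal_prob_one_empties_final_day(self):
        cfg = SimulationConfig(seed=6, n_library=60, n_vdom=30, n_noise_peaks=0,
                               vdom_removal_prob=1.0, mass_jitter_ppm_sd=0.0)
        truth = generate_formula_library(cfg)
        assert truth.removed_set == truth.vdom_set
        spectra, metas = simulate_experiment(truth)
        vdom_mz = {
            round(neutral_mass_to_mz(monoisotopic_mass(f)), 9) for f in truth.vdom
        }
        for sp, m in zip(spectra, metas):
            if m.is_blank or m.day != 55:
                continue
            present = {round(p.mz, 9) for p in sp.peaks}
            assert not present & vdom_mz

    def test_lysis_pulse_only_in_treatment_of_lysis_depth(self):
        cfg = SimulationConfig(seed=8, n_library=60, n_vdom=40, n_noise_peaks=0,
                               mass_jitter_ppm_sd=0.0)
        truth = generate_formula_library(cfg)
        spectra, metas = simulate_experiment(truth)
        vdom_mz = {
            round(neutral_mass_to_mz(monoisotopic_mass(f)), 9) for f in truth.vdom
        }
        for sp, m in zip(spectra, metas):
            if m.is_blank:
                continue
            present = {round(p.mz, 9) for p in sp.peaks}
            hit = len(present & vdom_mz)
            if m.arm == "treatment" and m.depth_label == cfg.lysis_depth and m.day == 6:
                assert hit > 0.8 * cfg.n_vdom
            elif m.arm == "control" or m.depth_label != cfg.lysis_depth or m.day == 0:
                assert hit == 0

    def test_blank_contaminant_placement(self, small_config, small_truth, small_experiment):
        spectra, metas = small_experiment
        blanks = [sp for sp, m in zip(spectra, metas) if m.is_blank]
        assert len(blanks) == small_config.n_blanks
        huge = [
            sum(p.snr >= small_config.blank_shared_snr for p in sp.peaks)
            for sp in blanks
        ]
        # each shared contaminant appears in exactly blank_shared_hits blanks
        assert sum(huge) == small_config.n_blank_shared * small_config.blank_shared_hits


class TestOtuScenarios:
    def test_bloom_decreases_evenness(self):
        otu = generate_otu_table("bloom", seed=3)
        counts = otu.drop(columns="taxonomy")
        j = [pielou(counts[c].to_numpy()) for c in counts.columns]
        assert j[-1] < j[0] - 0.2

    def test_stabilized_keeps_evenness(self):
        otu = generate_otu_table("stabilized", seed=3)
        counts = otu.drop(columns="taxonomy")
        j = [pielou(counts[c].to_numpy()) for c in counts.columns]
        assert max(j) - min(j) < 0.02

    def test_bloom_otus_are_gammaproteobacteria(self):
        otu = generate_otu_table("bloom", seed=3)
        counts = otu.drop(columns="taxonomy")
        top = counts["d55"].nlargest(3).index
        assert (otu.loc[top, "taxonomy"] == "Gammaproteobacteria").all()

    def test_validation_and_determinism(self):
        with pytest.raises(ValueError):
            generate_otu_table("chaos")
        a = generate_otu_table("bloom", seed=4)
        b = generate_otu_table("bloom", seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestEnvTable:
    def test_zero_noise_is_exactly_linear(self, small_experiment):
        _, metas = small_experiment
        env = generate_env_table(metas, seed=0, noise_sd=0.0)
        assert list(env.columns) == list(ENV_PARAMETERS)
        sub = env.loc[[f"surface_control_d{d:02d}_r1" for d in (0, 6, 14, 55)]]
        doc = sub["DOC"].to_numpy()
        days = np.array([0, 6, 14, 55], dtype=float)
        slope = (doc[1] - doc[0]) / 6.0
        np.testing.assert_allclose(doc, doc[0] + slope * days, rtol=1e-12)

    def test_blanks_excluded_and_rows_complete(self, small_experiment):
        _, metas = small_experiment
        env = generate_env_table(metas, seed=1)
        assert len(env) == sum(not m.is_blank for m in metas)
        assert env.notna().all().all()
        assert (env > 0).all().all()

    def test_determinism(self, small_experiment):
        _, metas = small_experiment
        pd.testing.assert_frame_equal(
            generate_env_table(metas, seed=2), generate_env_table(metas, seed=2)
        )
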
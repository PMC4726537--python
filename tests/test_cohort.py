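"""Tests of the synthetic cohort generator and its calibration."""

import numpy as np
import pandas as pd
import pytest

from mbdforest.cohort import (
    BIOCHEM,
    CohortConfig,
    DRUGS,
    TreatmentRule,
    config_from_yaml,
    config_to_yaml,
    generate_cohort,
    phosphate_response,
    structural_pth,
    summarize_cohort,
    write_records,
)


def _zeroed_config(**kwargs) -> CohortConfig:
    cfg = CohortConfig(**kwargs)
    return CohortConfig(
        n_patients=cfg.n_patients,
        months_per_patient=cfg.months_per_patient,
        seed=cfg.seed,
        coupling={k: 0.0 for k in cfg.coupling},
        noise_sd={k: 0.0 for k in cfg.noise_sd},
        patient_sd={k: 0.0 for k in cfg.patient_sd},
    )


class TestGenerate:
    def test_seed_determinism(self):
        cfg = CohortConfig(n_patients=10, months_per_patient=3, seed=1)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_row_count_and_uniqueness(self, small_cohort):
        assert len(small_cohort) == 150 * 6
        assert not small_cohort.duplicated(["patient_id", "month_index"]).any()

    def test_degenerate_config_pins_biochemistry_at_targets(self):
        """No noise and no couplings: biochemistry is constant at targets."""
        cfg = _zeroed_config(n_patients=20, months_per_patient=4, seed=0)
        table = generate_cohort(cfg)
        for var in BIOCHEM:
            target = cfg.marginal_targets[var][0]
            assert np.allclose(table[var], target), var

    def test_positive_support_and_ranges(self, small_cohort):
        for var in BIOCHEM:
            assert (small_cohort[var] > 0).all()
        assert (small_cohort["vintage"] >= 0).all()
        assert small_cohort["age"].between(18, 110, inclusive="neither").all()
        for d in DRUGS:
            assert set(small_cohort["drug_" + d].unique()) <= {0, 1}

    def test_confounding_by_indication(self, default_cohort):
        """Calcimimetic users have higher PTH (treatment given on indication)."""
        exposed = default_cohort.loc[default_cohort.drug_calcimimetic == 1, "pth"]
        unexposed = default_cohort.loc[default_cohort.drug_calcimimetic == 0, "pth"]
        assert exposed.mean() > unexposed.mean()

    def test_binder_confounding_sign(self, default_cohort):
        exposed = default_cohort.loc[default_cohort.drug_sevelamer == 1, "p"]
        unexposed = default_cohort.loc[default_cohort.drug_sevelamer == 0, "p"]
        assert exposed.mean() > unexposed.mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            CohortConfig(treatment_rules={"aspirin": TreatmentRule("pth", 300, 0.5)})
        with pytest.raises(ValueError):
            CohortConfig(treatment_rules={"calcitriol": TreatmentRule("pth", 300, 1.5)})
        with pytest.raises(ValueError):
            CohortConfig(drug_prevalence_targets={"sevelamer": -0.1})

    def test_clipping_is_logged(self):
        cfg = CohortConfig(n_patients=200, months_per_patient=5, seed=3)
        table = generate_cohort(cfg)
        assert isinstance(table.attrs["clipped"], dict)


class TestCalibration:
    def test_marginals_match_targets_at_scale(self, default_cohort):
        """At ~46k records every mean is within 2% and SD within 10%."""
        cfg = CohortConfig()
        s = summarize_cohort(default_cohort)
        assert len(default_cohort) >= 40_000
        for var, (mean, sd) in cfg.marginal_targets.items():
            assert abs(s["means"][var] - mean) <= 0.02 * mean, var
            assert abs(s["sds"][var] - sd) <= 0.10 * sd, var

    def test_male_fraction_and_prevalences(self, default_cohort):
        cfg = CohortConfig()
        s = summarize_cohort(default_cohort)
        assert abs(s["male_fraction"] - 0.592) <= 0.02
        for drug, target in cfg.drug_prevalence_targets.items():
            assert abs(s["drug_prevalence"][drug] - target) <= 0.02, drug


class TestStructure:
    def test_phosphate_response_is_nonlinear(self):
        """Second difference of the noiseless P->PTH response is nonzero."""
        p = np.array([3.0, 4.7, 6.4])
        out = structural_pth(p)
        second_diff = out[2] - 2 * out[1] + out[0]
        assert abs(second_diff) > 1.0  # pg/mL, far from affine

    def test_phosphate_response_monotone_and_saturating(self):
        p = np.linspace(1, 12, 100)
        h = phosphate_response(p)
        assert np.all(np.diff(h) > 0)
        # slope at the extremes far below slope in the normal range
        assert (h[1] - h[0]) < 0.2 * (h[51] - h[50])

    def test_zero_coupling_removes_phosphate_effect(self):
        cfg = CohortConfig().with_coupling(p_to_pth=0.0)
        out = structural_pth(np.array([2.0, 8.0]), config=cfg)
        assert out[0] == pytest.approx(out[1])

    def test_unknown_coupling_rejected(self):
        with pytest.raises(KeyError):
            CohortConfig().with_coupling(nonexistent=1.0)


class TestSummarize:
    def test_single_record_moments(self, small_cohort):
        one = small_cohort.iloc[[0]]
        s = summarize_cohort(one)
        assert s["means"]["ca"] == pytest.approx(one["ca"].iloc[0])
        assert s["sds"]["ca"] == 0.0

    def test_hand_built_three_row_moments(self):
        table = pd.DataFrame(
            {
                "patient_id": [1, 1, 2],
                "month_index": [0, 1, 0],
                "age": [60.0, 60.0, 50.0],
                "gender": [1, 1, 0],
                "vintage": [100.0, 130.0, 2000.0],
                "ca": [9.0, 10.0, 11.0],
                "p": [4.0, 5.0, 6.0],
                "pth": [100.0, 200.0, 600.0],
                "alk_phos": [100.0, 100.0, 100.0],
                "potassium": [5.0, 5.0, 5.0],
                **{"drug_" + d: [1, 0, 0] for d in DRUGS},
            }
        )
        s = summarize_cohort(table)
        assert s["means"]["ca"] == pytest.approx(10.0)
        # population SD of (9, 10, 11) is sqrt(2/3)
        assert s["sds"]["ca"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert s["means"]["pth"] == pytest.approx(300.0)
        assert s["drug_prevalence"]["vitamin_d"] == pytest.approx(1 / 3)
        assert s["n_patients"] == 2

    def test_empty_table_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            summarize_cohort(small_cohort.iloc[0:0])


class TestIO:
    def test_config_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_patients=17, months_per_patient=2, seed=9)
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        back = config_from_yaml(path)
        assert back == cfg

    def test_records_csv_round_trip(self, tmp_path, small_cohort):
        from mbdforest.dataset import read_records

        path = tmp_path / "cohort.csv"
        write_records(small_cohort, path)
        back = read_records(path)
        pd.testing.assert_frame_equal(
            back.astype(small_cohort.dtypes), small_cohort, check_exact=False, rtol=1e-12
        )
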
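"""Tests of record loading, complete-case filtering, encoding, splitting."""

import numpy as np
import pandas as pd
import pytest

from mbdforest.cohort import COLUMNS, DRUGS, write_records
from mbdforest.dataset import (
    encode_features,
    feature_list,
    filter_complete,
    read_records,
    split_train_test,
)


@pytest.fixture
def three_rows(small_cohort):
    return small_cohort.iloc[:3].reset_index(drop=True)


class TestReadRecords:
    def test_fixture_round_trip(self, tmp_path, three_rows):
        path = tmp_path / "t.csv"
        write_records(three_rows, path)
        table = read_records(path)
        assert len(table) == 3
        assert table["pth"].tolist() == pytest.approx(three_rows["pth"].tolist())

    def test_missing_column_named_in_error(self, tmp_path, three_rows):
        path = tmp_path / "t.csv"
        three_rows.drop(columns=["pth"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="pth"):
            read_records(path)

    def test_extra_column_warns_not_fatal(self, tmp_path, three_rows):
        path = tmp_path / "t.csv"
        extra = three_rows.assign(comment=["a", "b", "c"])
        extra.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="comment"):
            table = read_records(path)
        assert len(table) == 3

    def test_non_numeric_biochemistry_reports_line(self, tmp_path, three_rows):
        path = tmp_path / "t.csv"
        bad = three_rows.copy().astype({"ca": object})
        bad.loc[1, "ca"] = "oops"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"'ca' at line\(s\) 3"):
            read_records(path)


class TestFilterComplete:
    def test_row_missing_vintage_dropped(self, three_rows):
        t = three_rows.copy()
        t.loc[1, "vintage"] = np.nan
        out = filter_complete(t)
        assert len(out) == 2
        assert 1 not in out["month_index"].tolist()

    def test_complete_table_is_identity(self, three_rows):
        pd.testing.assert_frame_equal(filter_complete(three_rows), three_rows)

    def test_overlapping_missingness_counts(self, small_cohort):
        """3 rows missing Ca, 2 missing PTH, 1 overlapping -> 6 of 10 left."""
        t = small_cohort.iloc[:10].reset_index(drop=True)
        t.loc[[0, 1, 2], "ca"] = np.nan
        t.loc[[2, 3], "pth"] = np.nan
        assert len(filter_complete(t)) == 6

    def test_idempotence(self, small_cohort):
        t = small_cohort.iloc[:20].reset_index(drop=True)
        t.loc[[4, 9], "gender"] = np.nan
        once = filter_complete(t)
        pd.testing.assert_frame_equal(filter_complete(once), once)

    def test_empty_result_warns(self, three_rows):
        t = three_rows.copy()
        t["ca"] = np.nan
        with pytest.warns(UserWarning, match="empty"):
            out = filter_complete(t)
        assert len(out) == 0


class TestEncodeFeatures:
    def test_default_pth_design_has_16_columns(self, three_rows):
        """Two retained biochemical inputs, AP, K, age, gender, vintage,
        month index and the 8 drug flags: 16 features for any output."""
        m = encode_features(three_rows, "pth")
        assert m.X.shape == (3, 16)
        assert "pth" not in m.feature_names
        assert set(["ca", "p", "alk_phos", "potassium", "age", "gender",
                    "vintage", "month_index"]) < set(m.feature_names)
        assert sum(f.startswith("drug_") for f in m.feature_names) == 8
        assert m.y.tolist() == three_rows["pth"].tolist()

    def test_figure_preset_has_14_columns(self, three_rows):
        m = encode_features(three_rows, "pth", include_potassium=False, include_time=False)
        assert m.X.shape[1] == 14
        assert "potassium" not in m.feature_names
        assert "month_index" not in m.feature_names

    def test_output_swap_symmetry(self, three_rows):
        """ca vs p outputs differ only in which biochemical column swaps."""
        m_ca = encode_features(three_rows, "ca")
        m_p = encode_features(three_rows, "p")
        assert "p" in m_ca.feature_names and "ca" not in m_ca.feature_names
        assert "ca" in m_p.feature_names and "p" not in m_p.feature_names
        shared = [f for f in m_ca.feature_names if f in m_p.feature_names]
        for f in shared:
            a = m_ca.X[:, m_ca.feature_names.index(f)]
            b = m_p.X[:, m_p.feature_names.index(f)]
            assert np.array_equal(a, b)

    def test_constant_gender_column(self, small_cohort):
        males = small_cohort[small_cohort.gender == 1].iloc[:5].reset_index(drop=True)
        m = encode_features(males, "pth")
        assert np.all(m.X[:, m.feature_names.index("gender")] == 1.0)

    def test_unknown_output_rejected(self, three_rows):
        with pytest.raises(ValueError, match="output_name"):
            encode_features(three_rows, "alk_phos")

    def test_encoding_is_information_preserving(self, three_rows):
        """Matrix plus output column reconstructs the numeric table."""
        m = encode_features(three_rows, "pth")
        frame = m.to_frame()
        for col in m.feature_names + ["pth"]:
            assert np.allclose(frame[col], three_rows[col].astype(float))

    def test_drop_feature(self, three_rows):
        m = encode_features(three_rows, "pth")
        reduced = m.drop_feature("potassium")
        assert reduced.X.shape[1] == 15
        assert "potassium" not in reduced.feature_names
        with pytest.raises(KeyError):
            m.drop_feature("bogus")


class TestSplit:
    def test_sizes_for_n10(self):
        sp = split_train_test(10, seed=0)
        assert sp.train_idx.size == 7
        assert sp.test_idx.size == 3

    def test_seed_determinism_and_disjointness(self):
        a = split_train_test(100, seed=3)
        b = split_train_test(100, seed=3)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.intersect1d(a.train_idx, a.test_idx).size == 0
        assert np.union1d(a.train_idx, a.test_idx).size == 100

    def test_each_record_tests_about_30_percent(self):
        """Over 1000 reseeded splits each record lands in test ~30%."""
        counts = np.zeros(10)
        for seed in range(1000):
            sp = split_train_test(10, seed=seed)
            counts[sp.test_idx] += 1
        freq = counts / 1000
        assert np.all(np.abs(freq - 0.3) < 0.05)

    def test_patient_blocked_split(self, small_cohort):
        t = small_cohort.iloc[:600]
        sp = split_train_test(len(t), seed=1, by_patient=t["patient_id"].to_numpy())
        train_pat = set(t["patient_id"].to_numpy()[sp.train_idx])
        test_pat = set(t["patient_id"].to_numpy()[sp.test_idx])
        assert not (train_pat & test_pat)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(9, seed=0)

    def test_export_csv(self, tmp_path):
        sp = split_train_test(20, seed=0)
        path = tmp_path / "split.csv"
        sp.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == 20
        assert (back["role"] == "test").sum() == 6
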
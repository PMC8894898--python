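import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hippoasym.io import ScanRecord
from hippoasym.robustness import (Session, build_sessions, compare_methods_paired,
                                  icc_2_1, icc_2_1_from_table, mape,
                                  per_session_errors)


def scan(subject, sid, date, group="HC"):
    return ScanRecord(subject, sid, date, group, 30.0, 1.5e6,
                      {"volume": (3500.0, 3500.0)})


D = datetime.date


class TestBuildSessions:
    def test_patient_same_day_rule(self):
        recs = [scan("p1", "a", D(2020, 1, 1), "HS-left"),
                scan("p1", "b", D(2020, 1, 1), "HS-left"),
                scan("p1", "c", D(2020, 2, 1), "HS-left")]
        sessions = build_sessions(recs)
        assert len(sessions) == 1
        assert sorted(sessions[0].scan_ids) == ["a", "b"]

    def test_hc_greedy_one_year_chaining(self):
        # scans at day 0, 200, 400: session anchored at day 0 absorbs day 200;
        # day 400 is > 365 from the anchor and stays alone (no session)
        recs = [scan("h1", "a", D(2020, 1, 1)),
                scan("h1", "b", D(2020, 1, 1) + datetime.timedelta(days=200)),
                scan("h1", "c", D(2020, 1, 1) + datetime.timedelta(days=400))]
        sessions = build_sessions(recs)
        assert len(sessions) == 1
        assert sorted(sessions[0].scan_ids) == ["a", "b"]

    def test_single_scan_no_session(self):
        assert build_sessions([scan("h1", "a", D(2020, 1, 1))]) == []

    def test_scan_order_by_date_then_id(self):
        recs = [scan("h1", "b", D(2020, 1, 5)),
                scan("h1", "a", D(2020, 1, 5)),
                scan("h1", "c", D(2020, 1, 1))]
        (sess,) = build_sessions(recs)
        assert sess.scan_ids == ["c", "a", "b"]


class TestMape:
    def test_identical_repeats_zero(self):
        sessions = [Session("s", "s-0", ["a", "b"])]
        assert mape(sessions, {"a": 100.0, "b": 100.0}) == 0.0

    def test_single_session_hand_value(self):
        sessions = [Session("s", "s-0", ["a", "b"])]
        # mu = 105; (5/105 + 5/105)/2 * 100 = 4.7619
        assert mape(sessions, {"a": 100.0, "b": 110.0}) == pytest.approx(
            4.7619, abs=1e-4)

    def test_two_session_average(self):
        sessions = [Session("s1", "s1-0", ["a", "b"]),
                    Session("s2", "s2-0", ["c", "d"])]
        values = {"a": 100.0, "b": 110.0, "c": 200.0, "d": 200.0}
        assert mape(sessions, values) == pytest.approx(2.3810, abs=1e-4)

    def test_zero_mean_rejected(self):
        sessions = [Session("s", "s-0", ["a", "b"])]
        with pytest.raises(ZeroDivisionError):
            mape(sessions, {"a": -1.0, "b": 1.0})

    @given(st.floats(0.1, 1000.0))
    def test_scale_invariance(self, k):
        sessions = [Session("s1", "s1-0", ["a", "b"]),
                    Session("s2", "s2-0", ["c", "d"])]
        values = {"a": 100.0, "b": 112.0, "c": 480.0, "d": 500.0}
        scaled = {key: k * v for key, v in values.items()}
        assert mape(sessions, scaled) == pytest.approx(
            mape(sessions, values), rel=1e-9)


def pingouin_icc2(table):
    """Independent ICC(2,1) oracle via pingouin's two-way ANOVA."""
    import pandas as pd
    import pingouin as pg

    n, k = table.shape
    df = pd.DataFrame({
        "targets": np.repeat(np.arange(n), k),
        "raters": np.tile(np.arange(k), n),
        "ratings": table.ravel(),
    })
    res = pg.intraclass_corr(df, targets="targets", raters="raters",
                             ratings="ratings")
    # two-way random, absolute agreement, single measurement: labelled
    # "ICC2" in older pingouin releases, "ICC(A,1)" in newer ones
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[sel, "ICC"].iloc[0])


class TestIcc:
    def test_perfect_agreement(self):
        table = np.array([[7.0, 7.0], [5.0, 5.0], [9.0, 9.0], [3.0, 3.0]])
        assert icc_2_1_from_table(table) == pytest.approx(1.0)

    def test_toy_table_matches_anova_oracle(self):
        table = np.array([[7.0, 8.0], [5.0, 5.0], [9.0, 10.0], [3.0, 3.0]])
        assert icc_2_1_from_table(table) == pytest.approx(
            pingouin_icc2(table), abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        k = int(rng.integers(2, 5))
        table = rng.normal(5, 2, size=(n, k))
        assert icc_2_1_from_table(table) == pytest.approx(
            pingouin_icc2(table), abs=1e-10)

    def test_planted_variance_components(self):
        """sigma_b^2 = 9, sigma_e^2 = 1 -> population ICC = 0.9."""
        rng = np.random.default_rng(42)
        n = 2000
        session_effect = rng.normal(0, 3.0, size=(n, 1))
        table = 10.0 + session_effect + rng.normal(0, 1.0, size=(n, 2))
        assert icc_2_1_from_table(table) == pytest.approx(0.9, abs=0.02)

    def test_sessions_use_first_two_scans(self):
        sessions = [Session("s1", "s1-0", ["a", "b", "x"]),
                    Session("s2", "s2-0", ["c", "d"]),
                    Session("s3", "s3-0", ["e", "f"])]
        values = {"a": 7.0, "b": 8.0, "x": 999.0, "c": 5.0, "d": 5.0,
                  "e": 9.0, "f": 10.0}
        table = np.array([[7.0, 8.0], [5.0, 5.0], [9.0, 10.0]])
        assert icc_2_1(sessions, values) == pytest.approx(
            icc_2_1_from_table(table))

    def test_recovery_over_seeds(self):
        """At the study's session count (n=41, k=2) the estimator mean is
        within 0.05 of the planted ICC."""
        for icc_true, sigma_b in ((0.5, 1.0), (0.9, 3.0)):
            est = []
            for s in range(200):
                rng = np.random.default_rng(1000 + s)
                table = (rng.normal(0, sigma_b, size=(41, 1))
                         + rng.normal(0, 1.0, size=(41, 2)))
                est.append(icc_2_1_from_table(table))
            assert abs(np.mean(est) - icc_true) < 0.05


class TestComparePaired:
    def test_identical_vectors_p_one(self):
        errs = {"m1": [1.0, 2.0, 3.0, 4.0], "m2": [1.0, 2.0, 3.0, 4.0]}
        assert compare_methods_paired(errs)[("m1", "m2")] == 1.0

    def test_constant_offset_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 3, 41)
        errs = {"m1": base, "m2": base + 1.0 + rng.normal(0, 0.01, 41)}
        assert compare_methods_paired(errs)[("m1", "m2")] < 1e-3

    def test_pairing_invariant_to_joint_permutation(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 3, 20)
        b = a + rng.normal(0.2, 0.3, 20)
        p1 = compare_methods_paired({"m1": a, "m2": b})[("m1", "m2")]
        perm = rng.permutation(20)
        p2 = compare_methods_paired({"m1": a[perm], "m2": b[perm]})[("m1", "m2")]
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_mismatched_sessions_rejected(self):
        with pytest.raises(ValueError, match="same sessions"):
            compare_methods_paired({"m1": [1.0, 2.0, 3.0], "m2": [1.0, 2.0]})


def test_per_session_errors_feed_mape(default_cohort):
    from hippoasym.robustness import build_sessions

    sessions = build_sessions(default_cohort)
    assert len(sessions) == 41  # the emulated study's session count
    values = {r.scan_id: r.measures["volume"][0] for r in default_cohort}
    errs = per_session_errors(sessions, values)
    assert len(errs) == 41
    assert mape(sessions, values) == pytest.approx(errs.mean())
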
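import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsiscreen import scores
from sepsiscreen.errors import ConfigurationError
from sepsiscreen.preprocess import (
    DEFAULT_RANGES,
    MissingStrategy,
    PlausibilityRanges,
    apply_missing_strategy,
    derive_consciousness,
    plausibility_filter,
    preprocess_cases,
    resolve_assessment,
    resolve_frame,
)
from sepsiscreen.vitals import NORMAL_VALUES, WORST_VALUES, Vitals


class TestPlausibilityFilter:
    def test_in_range_identity(self):
        v = Vitals(temp=36.9, rr=16, hr=80, sbp=120, spo2=98, gcs=15)
        assert plausibility_filter(v) == v

    @pytest.mark.parametrize(
        "vital,value",
        [("temp", 12.0), ("temp", 46.0), ("rr", 0.0), ("rr", 81.0), ("spo2", 101.0),
         ("spo2", 39.0), ("hr", 9.0), ("sbp", 321.0), ("gcs", 2.0), ("gcs", 16.0),
         ("gcs", 12.5)],
    )
    def test_out_of_range_to_missing(self, vital, value):
        v = Vitals(**{vital: value})
        assert plausibility_filter(v).get(vital) is None

    def test_boundaries_kept(self):
        v = Vitals(spo2=100.0, temp=25.0, rr=80.0, gcs=3.0)
        assert plausibility_filter(v) == v

    @settings(max_examples=100, deadline=None)
    @given(
        temp=st.one_of(st.none(), st.floats(0, 60)),
        rr=st.one_of(st.none(), st.floats(0, 200)),
        spo2=st.one_of(st.none(), st.floats(0, 130)),
    )
    def test_idempotent(self, temp, rr, spo2):
        v = Vitals(temp=temp, rr=rr, spo2=spo2)
        once = plausibility_filter(v)
        assert plausibility_filter(once) == once

    def test_invalid_range_config(self):
        with pytest.raises(ConfigurationError, match="lower"):
            PlausibilityRanges({**DEFAULT_RANGES.ranges, "temp": (45.0, 25.0)})


class TestResolveAssessment:
    def test_first_wins(self):
        resolved, prov = resolve_assessment(Vitals(hr=80), Vitals(hr=110))
        assert resolved.hr == 80 and prov["hr"] == "first"

    def test_second_fills_gap(self):
        resolved, prov = resolve_assessment(Vitals(), Vitals(hr=110))
        assert resolved.hr == 110 and prov["hr"] == "second"

    def test_both_missing(self):
        resolved, prov = resolve_assessment(Vitals(), Vitals())
        assert resolved.hr is None and prov["hr"] == "missing"

    def test_worst_of_both(self):
        resolved, prov = resolve_assessment(
            Vitals(hr=80, sbp=120, gcs=15), Vitals(hr=140, sbp=130, gcs=12),
            precedence="worst",
        )
        assert resolved.hr == 140 and prov["hr"] == "second"
        assert resolved.sbp == 120 and prov["sbp"] == "first"
        assert resolved.gcs == 12


class TestDeriveConsciousness:
    def test_documented_wins(self):
        assert derive_consciousness(Vitals(consciousness="V", gcs=15)) == "V"

    @pytest.mark.parametrize("gcs,expected", [(15, "A"), (14, "V"), (13, "V"), (12, "P"), (9, "P"), (8, "U"), (7, "U"), (3, "U")])
    def test_gcs_mapping(self, gcs, expected):
        assert derive_consciousness(Vitals(gcs=gcs)) == expected

    def test_both_missing(self):
        assert derive_consciousness(Vitals()) is None

    def test_confusion_never_derived(self):
        for gcs in range(3, 16):
            assert derive_consciousness(Vitals(gcs=gcs)) != "C"


def _resolved_row(**missing):
    base = {
        "case_id": "x", "age": 60.0, "staff": "PM",
        "rr": 18.0, "spo2": 95.0, "on_oxygen": False, "sbp": 110.0,
        "hr": 95.0, "temp": 38.2, "gcs": 14.0, "consciousness": "V",
    }
    base.update(missing)
    df = pd.DataFrame([base])
    df["on_oxygen"] = df["on_oxygen"].astype("boolean")
    for v in ("rr", "spo2", "sbp", "hr", "temp", "gcs"):
        df[v] = pd.to_numeric(df[v])
        df[f"{v}_src"] = "first"
    df["on_oxygen_src"] = "first"
    df["consciousness_src"] = "first"
    return df


class TestStrategies:
    def test_normal_table_scores_zero_everywhere(self):
        v = Vitals(**NORMAL_VALUES)
        for tool in scores.TOOLS:
            assert scores.compute_score(tool, v) == 0

    def test_worst_table_attains_max(self):
        v = Vitals(**WORST_VALUES)
        assert scores.qsofa(v) == 3
        assert scores.sirs_prehospital(v) == 3
        assert scores.mews_prehospital(v) == 14
        assert scores.news2(v) == 20

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ConfigurationError, match="strategy"):
            MissingStrategy(name="mice")

    def test_bad_normal_table_rejected(self):
        with pytest.raises(ConfigurationError, match="normal_values"):
            MissingStrategy(name="normal", normal_values={**NORMAL_VALUES, "rr": 30.0})

    def test_missing_as_normal_fills_zero_scoring_value(self):
        df = _resolved_row(temp=np.nan)
        out = apply_missing_strategy(df, MissingStrategy("normal"))
        assert out["temp"].iloc[0] == 37.0
        assert out["temp_src"].iloc[0] == "imputed-missing_as_normal"

    def test_missing_as_worst_fills_max_scoring_value(self):
        df = _resolved_row(rr=np.nan)
        out = apply_missing_strategy(df, MissingStrategy("worst"))
        rr = out["rr"].iloc[0]
        from sepsiscreen.tables import default_tables

        assert default_tables()["news2"].components["rr"].lookup(rr) == 3
        assert default_tables()["mews"].components["rr"].lookup(rr) == 3
        assert default_tables()["qsofa"].components["rr"].lookup(rr) == 1
        assert default_tables()["sirs"].components["rr"].lookup(rr) == 1

    def test_complete_case_retains_full_record(self):
        df = _resolved_row()
        out = apply_missing_strategy(df, MissingStrategy("complete_case"))
        assert not out["excluded"].iloc[0]
        assert out["rr"].iloc[0] == 18.0

    def test_complete_case_excludes_any_missing_required(self):
        for vital, value in [("rr", np.nan), ("spo2", np.nan), ("on_oxygen", pd.NA), ("temp", np.nan)]:
            df = _resolved_row(**{vital: value})
            out = apply_missing_strategy(df, MissingStrategy("complete_case"))
            assert out["excluded"].iloc[0], vital

    def test_complete_case_mentation_either_channel_suffices(self):
        df = _resolved_row(gcs=np.nan)
        out = apply_missing_strategy(df, MissingStrategy("complete_case"))
        assert not out["excluded"].iloc[0]
        df = _resolved_row(gcs=np.nan, consciousness=None)
        out = apply_missing_strategy(df, MissingStrategy("complete_case"))
        assert out["excluded"].iloc[0]


class TestHotdeck:
    def _cohort_with_gaps(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(n)],
                "age": rng.integers(18, 100, n).astype(float),
                "staff": rng.choice(["PM", "EP"], n),
                "rr": rng.integers(8, 40, n).astype(float),
                "spo2": rng.integers(80, 101, n).astype(float),
                "on_oxygen": pd.array(rng.random(n) < 0.2, dtype="boolean"),
                "sbp": rng.integers(80, 200, n).astype(float),
                "hr": rng.integers(50, 140, n).astype(float),
                "temp": np.round(rng.uniform(35, 40, n), 1),
                "gcs": rng.integers(3, 16, n).astype(float),
            }
        )
        df["consciousness"] = rng.choice(["A", "V", "P", "U"], n)
        for v in ("rr", "spo2", "on_oxygen", "sbp", "hr", "temp", "gcs", "consciousness"):
            df[f"{v}_src"] = "first"
        # knock out ~30% of temps and some oxygen flags
        gone = rng.random(n) < 0.3
        df.loc[gone, "temp"] = np.nan
        df.loc[gone, "on_oxygen"] = pd.NA
        return df

    def test_deterministic_under_fixed_seed(self):
        df = self._cohort_with_gaps()
        a = apply_missing_strategy(df, MissingStrategy("hotdeck", seed=42))
        b = apply_missing_strategy(df, MissingStrategy("hotdeck", seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = apply_missing_strategy(df, MissingStrategy("hotdeck", seed=43))
        assert not a["temp"].equals(c["temp"])

    def test_imputed_values_come_from_donors(self):
        df = self._cohort_with_gaps()
        out = apply_missing_strategy(df, MissingStrategy("hotdeck", seed=1))
        assert out["temp"].notna().all()
        donors = set(df["temp"].dropna())
        imputed = out.loc[df["temp"].isna(), "temp"]
        assert set(imputed).issubset(donors)

    def test_empty_stratum_falls_back_to_global_pool(self, caplog):
        df = self._cohort_with_gaps(n=50)
        df["staff"] = "PM"
        df.loc[df.index[:5], "staff"] = "EP"
        df.loc[df["staff"] == "EP", "temp"] = np.nan  # no EP donors at all
        with caplog.at_level(logging.WARNING, logger="sepsiscreen.preprocess"):
            out = apply_missing_strategy(df, MissingStrategy("hotdeck", seed=1))
        assert out["temp"].notna().all()
        assert any("global pool" in r.message for r in caplog.records)


class TestDominance:
    def test_normal_strategy_scores_are_minimal(self, gappy_study):
        cases, outcomes, _ = gappy_study
        resolved = resolve_frame(cases)
        base = apply_missing_strategy(resolved, MissingStrategy("normal"))
        panel_normal = scores.score_panel(base, "normal")
        for other in ("hotdeck", "worst"):
            out = apply_missing_strategy(resolved, MissingStrategy(other, seed=9))
            panel = scores.score_panel(out, other)
            for tool in scores.TOOLS:
                assert (panel_normal[tool] <= panel[tool]).all(), (other, tool)

    def test_no_missing_after_any_imputing_strategy(self, gappy_study):
        cases, _, _ = gappy_study
        for name in ("normal", "hotdeck", "worst"):
            out = preprocess_cases(cases, name, seed=2)
            for vital in ("rr", "spo2", "on_oxygen", "sbp", "hr", "temp", "gcs", "consciousness"):
                assert out[vital].notna().all(), (name, vital)


def test_resolve_frame_provenance(gappy_study):
    cases, _, _ = gappy_study
    resolved = resolve_frame(cases)
    assert set(resolved["temp_src"]) <= {"first", "second", "missing"}
    assert set(resolved["consciousness_src"]) <= {"first", "second", "missing", "derived"}
    # provenance "missing" exactly where value is missing
    assert ((resolved["temp_src"] == "missing") == resolved["temp"].isna()).all()


def test_resolve_frame_filters_implausible(gappy_study):
    cases, _, log = gappy_study
    assert len(log) > 0
    resolved = resolve_frame(cases)
    for vital in ("rr", "spo2", "sbp", "hr", "temp", "gcs"):
        vals = resolved[vital].dropna()
        lo, hi = DEFAULT_RANGES.ranges[vital]
        assert ((vals >= lo) & (vals <= hi)).all(), vital
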
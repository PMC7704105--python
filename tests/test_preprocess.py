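"""Cleaning rules: age selection, adult filter, summaries, eligibility."""

import numpy as np
import pandas as pd
import pytest

from dimorph.preprocess import (
    apply_eligibility_filters,
    filter_adults,
    preprocess,
    select_closest_to_target_age,
    summarize_populations,
)


def _rec(animal, trait, age, value=1.0, sex="male", strain="s1", inst="i1"):
    return dict(animal_id=animal, sex=sex, strain=strain, institution=inst,
                age_days=age, trait_id=trait, value=value)


class TestClosestAge:
    def test_picks_nearest_measurement(self):
        df = pd.DataFrame([_rec("a", "t", 90.0), _rec("a", "t", 140.0)])
        out = select_closest_to_target_age(df)
        assert out["age_days"].tolist() == [90.0]

    def test_tie_broken_by_earlier_age(self):
        df = pd.DataFrame([_rec("a", "t", 105.0), _rec("a", "t", 95.0)])
        out = select_closest_to_target_age(df)
        assert out["age_days"].tolist() == [95.0]

    def test_single_measurement_identity(self):
        df = pd.DataFrame([_rec("a", "t", 123.0)])
        pd.testing.assert_frame_equal(select_closest_to_target_age(df), df)

    def test_empty_in_empty_out(self):
        df = pd.DataFrame(columns=["animal_id", "trait_id", "age_days"])
        assert select_closest_to_target_age(df).empty

    def test_per_animal_per_trait(self):
        df = pd.DataFrame([
            _rec("a", "t1", 90.0), _rec("a", "t1", 101.0),
            _rec("a", "t2", 300.0), _rec("b", "t1", 400.0),
        ])
        out = select_closest_to_target_age(df)
        assert len(out) == 3
        assert out.loc[out["trait_id"] == "t1", "age_days"].tolist() == [101.0, 400.0]


class TestAdultFilter:
    @pytest.mark.parametrize("age,kept", [(99.9, False), (100.0, True), (500.0, True), (501.0, False)])
    def test_inclusive_bounds(self, age, kept):
        df = pd.DataFrame([_rec("a", "t", age)])
        assert (len(filter_adults(df)) == 1) is kept

    def test_unsexed_and_missing_values_dropped(self):
        df = pd.DataFrame([
            _rec("a", "t", 200.0, sex="male"),
            _rec("b", "t", 200.0, sex=""),
            {**_rec("c", "t", 200.0), "sex": np.nan},
            _rec("d", "t", 200.0, value=np.nan),
        ])
        out = filter_adults(df)
        assert out["animal_id"].tolist() == ["a"]


class TestSummaries:
    def test_hand_arithmetic(self):
        df = pd.DataFrame(
            [_rec("a", "t", 150, v, "male") for a, v in zip("abc", [1.0, 2.0, 3.0])]
            + [_rec(a, "t", 150, v, "female") for a, v in zip("xy", [4.0, 6.0])]
        )
        out = summarize_populations(df)
        row = out.iloc[0]
        assert row["n_m"] == 3 and row["mean_m"] == 2.0 and row["sd_m"] == 1.0
        assert row["n_f"] == 2 and row["mean_f"] == 5.0 and row["sd_f"] == pytest.approx(np.sqrt(2))

    def test_one_sex_absent_gets_zero_count(self):
        df = pd.DataFrame([_rec("a", "t", 150, 1.0, "male")])
        out = summarize_populations(df)
        assert out.iloc[0]["n_f"] == 0

    def test_constant_values_give_zero_sd(self):
        df = pd.DataFrame([_rec(a, "t", 150, 7.0, "male") for a in "abc"])
        assert summarize_populations(df).iloc[0]["sd_m"] == 0.0


def _summary_row(trait="t", strain="s", inst="i1", n_m=10, n_f=10,
                 mean_m=5.0, mean_f=4.0, sd_m=1.0, sd_f=1.0):
    return dict(trait_id=trait, strain=strain, institution=inst,
                population_id=f"{strain}:{inst}", n_m=n_m, mean_m=mean_m, sd_m=sd_m,
                n_f=n_f, mean_f=mean_f, sd_f=sd_f)


class TestEligibility:
    def test_min_per_sex_rule(self):
        df = pd.DataFrame([
            _summary_row(inst="i1"), _summary_row(inst="i2", n_m=6, n_f=5),
            _summary_row(inst="i3"),
        ])
        kept, log = apply_eligibility_filters(df)
        assert len(kept) == 2
        assert log["reason"].tolist() == ["min_per_sex"]

    def test_single_institution_trait_dropped(self):
        df = pd.DataFrame([
            _summary_row(trait="t1", strain="s1", inst="i1"),
            _summary_row(trait="t1", strain="s2", inst="i1"),
            _summary_row(trait="t2", inst="i1"), _summary_row(trait="t2", inst="i2"),
        ])
        kept, log = apply_eligibility_filters(df)
        assert set(kept["trait_id"]) == {"t2"}
        assert (log["reason"] == "single_institution").sum() == 2

    def test_fixed_trait_dropped(self):
        df = pd.DataFrame([
            _summary_row(trait="t1", inst="i1", sd_m=0.0),
            _summary_row(trait="t1", inst="i2"),
            _summary_row(trait="t2", inst="i1"), _summary_row(trait="t2", inst="i2"),
        ])
        kept, log = apply_eligibility_filters(df)
        assert set(kept["trait_id"]) == {"t2"}
        assert (log["reason"] == "fixed_trait").sum() == 2

    def test_nonpositive_mean_dropped(self):
        df = pd.DataFrame([
            _summary_row(trait="t1", inst="i1", mean_f=-0.5),
            _summary_row(trait="t1", inst="i2"),
            _summary_row(trait="t2", inst="i1"), _summary_row(trait="t2", inst="i2"),
        ])
        kept, log = apply_eligibility_filters(df)
        assert set(kept["trait_id"]) == {"t2"}
        assert (log["reason"] == "nonpositive_mean").sum() == 2

    def test_idempotent(self):
        df = pd.DataFrame([
            _summary_row(inst="i1"), _summary_row(inst="i2", n_m=3),
            _summary_row(inst="i3"),
        ])
        once, _ = apply_eligibility_filters(df)
        twice, log2 = apply_eligibility_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty

    def test_conservation(self, small_dataset):
        """Kept + logged rows account for every input population."""
        from dimorph.preprocess import (
            filter_adults, select_closest_to_target_age, summarize_populations,
        )
        records, _, _ = small_dataset
        step = filter_adults(select_closest_to_target_age(records))
        summaries = summarize_populations(step)
        kept, log = apply_eligibility_filters(summaries)
        assert len(kept) + len(log) == len(summaries)


def test_full_chain_counts(small_dataset):
    records, _, _ = small_dataset
    summaries, exclusions = preprocess(records)
    assert not summaries.empty
    assert (summaries["n_m"] >= 6).all() and (summaries["n_f"] >= 6).all()
    assert (summaries.groupby("trait_id")["institution"].nunique() >= 2).all()
    assert set(exclusions.columns) == {"trait_id", "population_id", "reason"}
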
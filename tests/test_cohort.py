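from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import ploidykit as pk
from ploidykit.cohort import (
    abnormal_pn_age_regression,
    fit_age_model,
    or_ratio_between_ages,
    recombination_aneuploidy_association,
    recurrence_permutation_test,
    sart_group,
)


class TestSartGroups:
    @pytest.mark.parametrize(
        "age,cat",
        [
            (34.9, "<35"),
            (35.0, "35-37"),  # left boundary belongs to the named band
            (37.9, "35-37"),
            (38.0, "38-40"),
            (41.0, "41-42"),
            (42.9, "41-42"),
            (43.0, ">42"),
        ],
    )
    def test_boundaries(self, age, cat):
        assert sart_group([age])[0] == cat

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            sart_group([-1])


class TestAgeModel:
    def test_null_or_recovered(self):
        coh = pk.simulate_cohort(pk.CohortParams(or_per_year=1.0, base_rate=0.05), 2500, seed=100)
        m = fit_age_model(coh)
        lo, hi = m.ci["maternal_age"]
        assert lo <= 1.0 <= hi

    def test_generating_or_recovered_at_scale(self):
        # cohort at the clinical scale and effect size; refit recovers the OR
        coh = pk.simulate_cohort(pk.CohortParams(), 20_000, seed=101)
        m = fit_age_model(coh, "any_ploidy_abnormality")
        lo, hi = m.ci["maternal_age"]
        assert lo <= 1.046 <= hi

    def test_collinear_paternal_age_attenuates_multivariately(self):
        # only maternal age is causal; paternal age = maternal + noise
        coh = pk.simulate_cohort(
            pk.CohortParams(or_per_year=1.12, base_rate=0.05,
                            paternal_offset_sd=2.0), 8000, seed=102
        )
        uni = fit_age_model(coh, covariates=("paternal_age",))
        multi = fit_age_model(coh, covariates=("maternal_age", "paternal_age"))
        assert uni.p_values["paternal_age"] < 0.001  # significant univariately
        assert multi.p_values["paternal_age"] > uni.p_values["paternal_age"]
        assert abs(np.log(multi.odds_ratios["paternal_age"])) < abs(
            np.log(uni.odds_ratios["paternal_age"])
        )

    def test_empty_class_informative_failure(self):
        coh = pk.simulate_cohort(pk.CohortParams(base_rate=0.2), 200, seed=103)
        coh["label"] = "diploid"
        with pytest.raises(ValueError, match="empty class"):
            fit_age_model(coh)

    @pytest.mark.parametrize("orr,a1,a2,want", [(1.0, 30, 40, 1.0), (2.0, 30, 31, 2.0)])
    def test_or_ratio_trivial(self, orr, a1, a2, want):
        m = fit_age_model(pk.simulate_cohort(pk.CohortParams(base_rate=0.1), 500, seed=104))
        m.odds_ratios["maternal_age"] = orr
        assert or_ratio_between_ages(m, a1, a2) == pytest.approx(want)

    def test_or_ratio_decade(self):
        # OR 1.059/year compounds to ~1.77 over ten years
        m = fit_age_model(pk.simulate_cohort(pk.CohortParams(base_rate=0.1), 500, seed=105))
        m.odds_ratios["maternal_age"] = 1.059
        assert or_ratio_between_ages(m, 30, 40) == pytest.approx(1.059**10)
        assert round(or_ratio_between_ages(m, 30, 40), 2) == 1.77


def _toy_cohort(sizes, abnormal_positions, age=30.0):
    rows = []
    k = 0
    for c, size in enumerate(sizes):
        for e in range(size):
            rows.append(
                {
                    "cycle_id": c,
                    "embryo_id": f"c{c}e{e}",
                    "maternal_age": age,
                    "paternal_age": age + 2,
                    "label": "triploid" if k in abnormal_positions else "diploid",
                    "sex_karyotype": "XXX",
                }
            )
            k += 1
    return pd.DataFrame(rows)


class TestRecurrence:
    def test_singleton_cycles_cannot_recur(self):
        coh = _toy_cohort([1] * 30, {0, 5})
        res = recurrence_permutation_test(coh, 500, seed=110)
        assert res[res["recurrence_k"] == 2].empty  # k=2 never observed
        k1 = res[res["recurrence_k"] == 1].iloc[0]
        assert k1["observed_cycles"] == 2 and k1["p_raw"] == pytest.approx(1.0, abs=0.01)

    def test_matches_exhaustive_enumeration(self):
        # 3 cycles of size 2, 2 abnormal embryos placed in one cycle:
        # P(some cycle holds both) over all C(6,2)=15 placements is 3/15
        coh = _toy_cohort([2, 2, 2], {0, 1})
        res = recurrence_permutation_test(coh, 20_000, seed=111)
        exact = (
            sum(
                1
                for pair in combinations(range(6), 2)
                if pair[0] // 2 == pair[1] // 2
            )
            / 15
        )
        p2 = res[res["recurrence_k"] == 2]["p_raw"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(p2 - exact) < 4 * se + 1e-3

    def test_clustered_risk_detected(self):
        # 1 % of couples carry a 40x odds multiplier: some k>=3 cell must
        # survive Bonferroni
        coh = pk.simulate_cohort(
            pk.CohortParams(base_rate=0.01, risk_fraction=0.01, risk_multiplier=40.0),
            6000, seed=112,
        )
        res = recurrence_permutation_test(coh, 2000, seed=113)
        hits = res[(res["recurrence_k"] >= 3) & res["significant"]]
        assert not hits.empty

    def test_observed_counts_non_increasing_in_k(self):
        coh = pk.simulate_cohort(pk.CohortParams(base_rate=0.08), 800, seed=114)
        res = recurrence_permutation_test(coh, 200, seed=115)
        for _, grp in res.groupby("age_category"):
            assert np.all(np.diff(grp.sort_values("recurrence_k")["observed_cycles"]) <= 0)

    def test_p_values_bounded_below(self):
        coh = _toy_cohort([2, 2, 2], {0, 1})
        res = recurrence_permutation_test(coh, 1000, seed=116)
        assert (res["p_raw"] >= 1 / 1001).all() and (res["p_raw"] <= 1).all()

    def test_too_few_permutations_refused(self):
        with pytest.raises(ValueError, match="n_perm"):
            recurrence_permutation_test(_toy_cohort([2, 2], {0}), 50, seed=117)


class TestAbnormalPnRegression:
    def test_recovers_age_trend_in_synthetic_zygotes(self):
        # abnormal-PN counts generated with a 5 %/year rate increase
        rng = np.random.default_rng(120)
        n = 3000
        age = rng.normal(35.65, 2.9, n).clip(20, 47)
        n_zyg = 1 + rng.poisson(5, n)
        rate = 0.1 * np.exp(np.log(1.05) * (age - 35.65))
        zyg = pd.DataFrame(
            {"maternal_age": age, "n_zygotes": n_zyg,
             "n_abnormal_pn": rng.poisson(rate * n_zyg)}
        )
        res = abnormal_pn_age_regression(zyg)
        assert res["p_value"] < 0.001
        assert res["rate_ratio_per_year"] == pytest.approx(1.05, abs=0.02)

    def test_flat_rate_is_null(self):
        rng = np.random.default_rng(121)
        n = 1500
        zyg = pd.DataFrame(
            {"maternal_age": rng.normal(35.0, 3.0, n),
             "n_zygotes": 1 + rng.poisson(5, n),
             "n_abnormal_pn": rng.poisson(0.2, n)}
        )
        res = abnormal_pn_age_regression(zyg)
        assert res["p_value"] > 0.01


class TestRecombinationAneuploidyAssociation:
    def test_identical_groups_null(self):
        df = pd.DataFrame(
            {
                "recombination_events": [5, 20] * 20,
                "aneuploidy_count": [1, 2] * 10 + [2, 1] * 10,
            }
        )
        res = recombination_aneuploidy_association(df)
        assert res["p_low_vs_high"] == pytest.approx(1.0)
        assert res["low_group_mean_aneuploidy"] == res["high_group_mean_aneuploidy"]

    def test_detects_constructed_association(self):
        rng = np.random.default_rng(118)
        events = rng.integers(0, 26, 300)
        counts = rng.poisson(np.maximum(3 - events / 10, 0.2))
        df = pd.DataFrame(
            {
                "recombination_events": events,
                "aneuploidy_count": counts,
                "meiotic_phase": np.where(events < 13, "MI", "MII"),
            }
        )
        res = recombination_aneuploidy_association(df)
        assert res["p_low_vs_high"] < 0.001
        assert res["low_group_mean_aneuploidy"] > res["high_group_mean_aneuploidy"]
        assert res["p_mi_vs_mii"] < 0.05

    def test_type_one_error_on_symmetric_null(self):
        rng = np.random.default_rng(119)
        rejections = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "recombination_events": rng.integers(0, 26, 60),
                    "aneuploidy_count": rng.poisson(1.5, 60),
                }
            )
            if recombination_aneuploidy_association(df)["p_low_vs_high"] < 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps < 0.05 + 3 * se

    def test_degenerate_group_rejected(self):
        df = pd.DataFrame({"recombination_events": [1, 1], "aneuploidy_count": [0, 1]})
        with pytest.raises(ValueError):
            recombination_aneuploidy_association(df)
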
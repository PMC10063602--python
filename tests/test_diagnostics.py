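"""Diagnostic battery: hand oracles, contract cases and positive controls."""

import math

import numpy as np
import pandas as pd
import pytest

from nmm import (
    Item,
    ItemBank,
    Person,
    ResponseMatrix,
    ValidationError,
    class_intervals,
    cml_fit,
    dif_anova,
    extreme_screen,
    local_dependency,
    person_measures,
    psi,
    smith_dimensionality,
    standardized_residuals,
    targeting_summary,
)
from nmm.diagnostics import (
    expected_probabilities,
    item_chi_square,
    item_fit_residuals,
)
from nmm.rasch import PersonMeasure
from conftest import simulate_flat


@pytest.fixture(scope="module")
def fitted(flat_cohort):
    """One calibrated model-true cohort with residuals precomputed."""
    rm, true, theta = flat_cohort
    rm = extreme_screen(rm).matrix
    bank = cml_fit(rm)
    measures = person_measures(rm, bank)
    z = standardized_residuals(rm, bank, measures)
    p = expected_probabilities(rm, bank, measures)
    return rm, bank, measures, z, p


class TestStandardizedResiduals:
    def test_pass_at_matched_location_gives_plus_one(self):
        bank = ItemBank([Item("a", difficulty=0.5), Item("b", difficulty=-0.5)])
        rm = ResponseMatrix([Person("p")], ["a", "b"], np.array([[1.0, 0.0]]))
        # force theta = 0 via a hand-made measure
        measures = [PersonMeasure("p", 1, ("a", "b"), 0.0, 1.0, False)]
        z = standardized_residuals(rm, bank, measures)
        p = 1 / (1 + math.exp(0.5))
        assert z.loc["p", "a"] == pytest.approx((1 - p) / math.sqrt(p * (1 - p)))

    def test_fail_one_logit_above_difficulty(self):
        bank = ItemBank([Item("a", difficulty=0.0), Item("b", difficulty=5.0)])
        rm = ResponseMatrix([Person("p")], ["a", "b"], np.array([[0.0, 1.0]]))
        measures = [PersonMeasure("p", 1, ("a", "b"), 1.0, 1.0, False)]
        z = standardized_residuals(rm, bank, measures)
        assert z.loc["p", "a"] == pytest.approx(-1.6487, abs=1e-4)

    def test_missing_stays_missing_and_mean_near_zero(self, fitted):
        rm, bank, measures, z, _ = fitted
        assert z.isna().to_numpy().sum() == 0  # complete design here
        assert abs(np.nanmean(z.to_numpy())) < 0.05


class TestClassIntervals:
    def test_equal_counts_and_ordered_boundaries(self, fitted):
        _, _, measures, _, _ = fitted
        ci = class_intervals(measures, 5)
        counts = ci.assignment.value_counts()
        assert counts.max() - counts.min() <= 1
        assert (np.diff(ci.boundaries) > 0).all()

    def test_too_few_classes_rejected(self, fitted):
        _, _, measures, _, _ = fitted
        with pytest.raises(ValidationError):
            class_intervals(measures, 1)


class TestItemFit:
    def test_misfitting_coin_flip_item_flagged_positive(self, flat_cohort):
        rm, true, theta = flat_cohort
        vals = rm.values.copy()
        rng = np.random.default_rng(99)
        vals[:, 3] = (rng.random(rm.n_persons) < 0.5).astype(float)
        noisy = ResponseMatrix(rm.persons, rm.items, vals)
        noisy = extreme_screen(noisy).matrix
        bank = cml_fit(noisy)
        measures = person_measures(noisy, bank)
        z = standardized_residuals(noisy, bank, measures)
        p = expected_probabilities(noisy, bank, measures)
        fit = item_fit_residuals(z, p)
        assert fit.loc["i03", "fit_residual"] > 2.5
        assert fit.loc["i03", "flagged"]

    def test_duplicated_item_overfits_negative_on_average(self):
        pair, others = [], []
        for seed in range(200, 205):
            rm, true, theta = simulate_flat(seed=seed)
            vals = rm.values.copy()
            vals[:, 5] = vals[:, 4]
            dup = extreme_screen(ResponseMatrix(rm.persons, rm.items, vals)).matrix
            bank = cml_fit(dup)
            measures = person_measures(dup, bank)
            z = standardized_residuals(dup, bank, measures)
            p = expected_probabilities(dup, bank, measures)
            fit = item_fit_residuals(z, p)
            pair.append(fit.loc[["i04", "i05"], "fit_residual"].mean())
            others.append(fit["fit_residual"].drop(["i04", "i05"]).mean())
        assert np.mean(pair) < -0.5
        assert np.mean(pair) < np.mean(others)

    def test_low_n_flag(self, fitted):
        rm, bank, measures, z, p = fitted
        small = item_fit_residuals(z.iloc[:5], p.iloc[:5])
        assert small["low_n"].all()


class TestItemChiSquare:
    def test_hand_computed_table(self):
        # 6 persons, 2 classes; probabilities fixed by a hand-made bank/theta
        bank = ItemBank([Item("a", difficulty=0.0), Item("b", difficulty=0.0)])
        thetas = [-1.0, -1.0, -1.0, 1.0, 1.0, 1.0]
        persons = [Person(f"p{i}") for i in range(6)]
        vals = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [1, 1], [0, 1]], dtype=float
        )
        rm = ResponseMatrix(persons, ["a", "b"], vals)
        measures = [
            PersonMeasure(f"p{i}", int(vals[i].sum()), ("a", "b"), t, 1.0, False)
            for i, t in enumerate(thetas)
        ]
        res = item_chi_square(rm, bank, measures, n_classes=2)
        p_lo = 1 / (1 + math.exp(1.0))
        p_hi = 1 / (1 + math.exp(-1.0))
        v = 3 * p_lo * (1 - p_lo)  # same for both classes
        # item a: class totals O = (1, 2); E = 3*p
        chi_a = (1 - 3 * p_lo) ** 2 / v + (2 - 3 * p_hi) ** 2 / v
        assert res.loc["a", "chi_square"] == pytest.approx(chi_a, abs=1e-10)
        assert res.loc["a", "chi_df"] == 1

    def test_perfect_fit_gives_zero(self):
        # deterministic toy where observed class totals equal expectation
        bank = ItemBank([Item("a", difficulty=0.0), Item("b", difficulty=0.0)])
        persons = [Person(f"p{i}") for i in range(4)]
        vals = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        rm = ResponseMatrix(persons, ["a", "b"], vals)
        measures = [
            PersonMeasure(f"p{i}", 1, ("a", "b"), 0.0, 1.0, False) for i in range(4)
        ]
        res = item_chi_square(rm, bank, measures, n_classes=2)
        assert res.loc["a", "chi_square"] == pytest.approx(0.0, abs=1e-12)

    def test_bonferroni_scales_with_item_count(self, fitted):
        rm, bank, measures, _, _ = fitted
        res = item_chi_square(rm, bank, measures)
        ok = res["chi_p"].notna()
        np.testing.assert_allclose(
            res.loc[ok, "chi_p_bonferroni"],
            np.minimum(1.0, res.loc[ok, "chi_p"] * rm.n_items),
        )


class TestDif:
    def test_single_group_rejected(self, fitted):
        rm, bank, measures, z, _ = fitted
        groups = pd.Series("HC", index=z.index)
        ci = class_intervals(measures, 5)
        with pytest.raises(ValidationError):
            dif_anova(z, groups, ci)

    def test_injected_uniform_dif_detected(self):
        # shift item 2 by +1 logit for the AD group only
        rng = np.random.default_rng(12)
        rm, true, theta = simulate_flat(seed=12)
        vals = rm.values.copy()
        ad = np.array([p.group == "AD" for p in rm.persons])
        shifted = 1 / (1 + np.exp(-(theta[ad] - (true[2] + 1.0))))
        vals[ad, 2] = (rng.random(int(ad.sum())) < shifted).astype(float)
        rm = extreme_screen(ResponseMatrix(rm.persons, rm.items, vals)).matrix
        bank = cml_fit(rm)
        measures = person_measures(rm, bank)
        z = standardized_residuals(rm, bank, measures)
        groups = rm.person_frame().set_index("person_id")["group"]
        ci = class_intervals(measures, 5)
        res = dif_anova(z, groups, ci)
        assert res.loc["i02", "dif_group_p_bonferroni"] < 0.05


class TestLocalDependency:
    def test_hand_pearson_matrix(self):
        z = pd.DataFrame(
            {
                "a": [0.5, -1.0, 1.5, -0.5, 0.2],
                "b": [0.4, -0.9, 1.2, -0.4, 0.1],
                "c": [-1.0, 1.0, -0.5, 0.5, 0.0],
            },
            index=[f"p{i}" for i in range(5)],
        )
        res = local_dependency(z)
        expected = np.corrcoef(z["a"], z["b"])[0, 1]
        assert res.corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert ("a", "b") in res.flagged_pairs  # near-duplicate columns

    def test_duplicated_item_pair_flagged(self, flat_cohort):
        rm, true, theta = flat_cohort
        vals = rm.values.copy()
        vals[:, 7] = vals[:, 6]
        dup = extreme_screen(ResponseMatrix(rm.persons, rm.items, vals)).matrix
        bank = cml_fit(dup)
        measures = person_measures(dup, bank)
        z = standardized_residuals(dup, bank, measures)
        res = local_dependency(z)
        assert ("i06", "i07") in res.flagged_pairs
        assert res.corr.loc["i06", "i07"] > 0.9

    def test_needs_three_items(self):
        z = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.1]})
        with pytest.raises(ValidationError):
            local_dependency(z)


class TestDimensionality:
    def test_two_factor_structure_detected(self, flat_cohort):
        rm, true, theta = flat_cohort
        rng = np.random.default_rng(21)
        # redraw the second half of the items from a weakly-correlated ability
        theta2 = 0.3 * theta + math.sqrt(1 - 0.09) * rng.normal(0, 1.5, len(theta))
        vals = rm.values.copy()
        cols = np.arange(10, 20)
        p2 = 1 / (1 + np.exp(-(theta2[:, None] - true[None, cols])))
        vals[:, cols] = (rng.random(p2.shape) < p2).astype(float)
        rm2 = extreme_screen(ResponseMatrix(rm.persons, rm.items, vals)).matrix
        bank = cml_fit(rm2)
        measures = person_measures(rm2, bank)
        z = standardized_residuals(rm2, bank, measures)
        res = smith_dimensionality(rm2, bank, z)
        assert res.status == "ok"
        assert res.pct_t_outside > 5.0

    def test_degenerate_split_reported_not_raised(self, fitted):
        rm, bank, measures, z, _ = fitted
        # force all loadings to one sign by feeding a rank-one residual frame
        base = np.linspace(-1, 1, len(z))
        zz = pd.DataFrame(
            {c: base * (k + 1) for k, c in enumerate(z.columns[:5])}, index=z.index
        )
        res = smith_dimensionality(rm.subset_items(list(z.columns[:5])), bank, zz)
        assert res.status == "degenerate"
        assert math.isnan(res.pct_t_outside)


class TestPsiAndTargeting:
    def test_psi_direct_formula(self):
        measures = [
            PersonMeasure(f"p{i}", 1, ("a",), t, math.sqrt(0.5), False)
            for i, t in enumerate([0.0, 2.0, -2.0, 1.0, -1.0])
        ]
        v = np.var([0.0, 2.0, -2.0, 1.0, -1.0], ddof=1)
        assert psi(measures) == pytest.approx((v - 0.5) / v)

    def test_psi_approaches_one_as_se_vanishes(self):
        thetas = [0.0, 2.0, -2.0, 1.0]
        for se, lo in ((0.5, 0.8), (0.05, 0.995), (0.005, 0.99995)):
            measures = [
                PersonMeasure(f"p{i}", 1, ("a",), t, se, False)
                for i, t in enumerate(thetas)
            ]
            assert psi(measures) > lo

    def test_psi_grows_with_cohort_spread(self):
        rng = np.random.default_rng(3)
        deltas = np.linspace(-2, 2, 15)
        values = []
        for sd in (0.5, 1.0, 2.0):
            rm, true, theta = simulate_flat(
                seed=3, n_persons=400, deltas=deltas, theta_sd=sd
            )
            rm = extreme_screen(rm).matrix
            bank = cml_fit(rm)
            values.append(psi(person_measures(rm, bank)))
        assert values[0] < values[1] < values[2]

    def test_psi_extreme_toggle_only_touches_extreme_rows(self, flat_cohort):
        rm, true, theta = flat_cohort
        bank = ItemBank(
            [Item(i, difficulty=float(d)) for i, d in zip(rm.items, true - true.mean())]
        )
        measures = person_measures(rm, bank)
        interior = [m for m in measures if not m.extreme]
        assert psi(measures, include_extremes=False) == pytest.approx(
            psi(interior, include_extremes=True)
        )

    def test_targeting_item_mean_zero_for_centred_bank(self, fitted):
        rm, bank, measures, _, _ = fitted
        summ = targeting_summary(measures, bank)
        assert summ.item_mean == pytest.approx(0.0, abs=1e-6)
        assert summ.person_range[0] < summ.person_mean < summ.person_range[1]

    def test_single_person_sd_undefined(self):
        bank = ItemBank([Item("a", difficulty=0.0)])
        measures = [PersonMeasure("p", 1, ("a",), 0.5, 1.0, False)]
        summ = targeting_summary(measures, bank)
        assert math.isnan(summ.person_sd)
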
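"""Central composite design, quadratic surface fitting, ANOVA, contouring."""

import numpy as np
import pandas as pd
import pytest

from hsiph import (CCDDesign, FactorSpec, QuadraticSurface, anova_quadratic,
                   code_transform, contour_grid, evaluate_surface,
                   fit_quadratic_surface, generate_ccd,
                   generate_rsm_responses, preset_factors, preset_surface)
from hsiph.rsm import PRESET_TABLE_UNCODED


@pytest.fixture(scope="module")
def design():
    return generate_ccd(seed=None)  # standard order


def random_surface(seed):
    rng = np.random.default_rng(seed)
    return QuadraticSurface(rng.normal(), rng.normal(size=5),
                            rng.normal(size=5), rng.normal(size=10))


class TestDesignStructure:
    def test_default_design_has_32_runs(self, design):
        assert design.n_runs == 32
        assert design.run_type.count("factorial") == 16
        assert design.run_type.count("axial") == 10
        assert design.run_type.count("center") == 6

    def test_factorial_rows_satisfy_the_defining_relation(self, design):
        factorial = design.coded[np.array(design.run_type) == "factorial"]
        assert np.allclose(factorial[:, 4],
                           np.prod(factorial[:, :4], axis=1))

    def test_axial_rows_have_one_coordinate_at_alpha(self, design):
        axial = design.coded[np.array(design.run_type) == "axial"]
        for row in axial:
            nonzero = row[row != 0]
            assert len(nonzero) == 1 and abs(nonzero[0]) == 2.0

    def test_coded_columns_are_balanced_and_orthogonal(self, design):
        assert np.allclose(design.coded.sum(axis=0), 0.0)
        factorial = design.coded[np.array(design.run_type) == "factorial"]
        gram = factorial.T @ factorial
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0)

    def test_shuffled_order_is_seed_reproducible_permutation(self, design):
        a = generate_ccd(seed=13)
        b = generate_ccd(seed=13)
        assert np.array_equal(a.coded, b.coded)
        # same multiset of runs as standard order
        key = lambda m: sorted(map(tuple, m))
        assert key(a.coded) == key(design.coded)

    def test_non_five_factor_input_rejected_by_default(self):
        with pytest.raises(ValueError, match="5 factors"):
            generate_ccd(factors=preset_factors()[:3])

    def test_verbatim_experiment_table_matches_exact_affine_design(self, design):
        # the published run table prints rounded uncoded levels; recode it,
        # confirm it is the same design, and bound the printing error
        factors = preset_factors()
        coded = np.array([[round(f.to_coded(v)) for f, v in zip(factors, row)]
                          for row in PRESET_TABLE_UNCODED], dtype=float)
        key = lambda m: sorted(map(tuple, m))
        assert key(coded) == key(design.coded)
        exact = np.array([[f.to_uncoded(c) for f, c in zip(factors, row)]
                          for row in coded])
        assert np.max(np.abs(exact - PRESET_TABLE_UNCODED)) <= 0.1


class TestCodeTransform:
    def test_treatment_time_plus_one_is_90_minutes(self):
        x5 = FactorSpec("X5", 75.0, 15.0, "min")
        assert code_transform(x5, 1.0, "to_uncoded") == 90.0

    def test_lactic_acid_axial_is_22_5(self):
        x4 = FactorSpec("X4", 19.50, 1.50, "mL/kg NaCl")
        assert code_transform(x4, 2.0, "to_uncoded") == 22.50

    def test_coded_zero_is_the_center_for_every_factor(self):
        for factor in preset_factors():
            assert code_transform(factor, 0.0, "to_uncoded") == factor.center

    def test_round_trip(self, rng):
        for factor in preset_factors():
            for coded in rng.uniform(-2, 2, size=5):
                back = factor.to_coded(factor.to_uncoded(coded))
                assert back == pytest.approx(coded, abs=1e-12)


class TestSurfaceFit:
    def test_noiseless_responses_recover_coefficients(self, design):
        for seed in range(5):
            truth = random_surface(seed)
            y = generate_rsm_responses(truth, design, 0.0, 0)
            fit = fit_quadratic_surface(design, y)
            rel = np.abs(fit.coefficients() - truth.coefficients()) / \
                np.maximum(np.abs(truth.coefficients()), 1e-12)
            assert np.max(rel) < 1e-6

    def test_published_surface_round_trips_through_the_design(self, design):
        truth = preset_surface()
        y = generate_rsm_responses(truth, design, 0.0, 0)
        fit = fit_quadratic_surface(design, y)
        rel = np.abs(fit.coefficients() - truth.coefficients()) / \
            np.maximum(np.abs(truth.coefficients()), 1e-12)
        assert np.max(rel) < 1e-6

    def test_constant_responses_give_intercept_only(self, design):
        fit = fit_quadratic_surface(design, np.full(32, 4.2))
        assert fit.beta0 == pytest.approx(4.2, abs=1e-8)
        assert np.allclose(fit.coefficients()[1:], 0.0, atol=1e-8)

    def test_coefficient_error_shrinks_with_noise(self, design):
        truth = random_surface(99)
        errs = []
        for sigma in (1e-2, 1e-4, 1e-6):
            y = generate_rsm_responses(truth, design, sigma, 12)
            fit = fit_quadratic_surface(design, y)
            errs.append(np.max(np.abs(fit.coefficients() - truth.coefficients())))
        assert errs[0] > errs[1] > errs[2]

    def test_response_count_mismatch_rejected(self, design):
        with pytest.raises(ValueError, match="responses"):
            fit_quadratic_surface(design, np.zeros(30))


class TestAnova:
    def test_df_column_matches_the_32_run_layout(self, design, rng):
        y = generate_rsm_responses(random_surface(1), design, 0.3, 5)
        table = anova_quadratic(design, y).set_index("source")
        assert table.loc["Model", "df"] == 20
        assert table.loc["Error", "df"] == 11
        assert table.loc["Lack of Fit", "df"] == 6
        assert table.loc["Pure Error", "df"] == 5
        assert table.loc["Total", "df"] == 31
        assert table.loc["Linear", "df"] == 5
        assert table.loc["2-Way Interaction", "df"] == 10

    def test_noiseless_responses_leave_no_residual(self, design):
        y = generate_rsm_responses(random_surface(2), design, 0.0, 0)
        table = anova_quadratic(design, y).set_index("source")
        assert table.loc["Error", "adj_SS"] < 1e-12

    def test_pure_error_equals_center_replicate_loop_oracle(self, design, rng):
        y = generate_rsm_responses(random_surface(3), design, 0.4, 7)
        table = anova_quadratic(design, y).set_index("source")
        center = y[np.array(design.run_type) == "center"]
        acc = 0.0
        for value in center:                           # independent accumulation
            acc += (value - center.mean()) ** 2
        assert table.loc["Pure Error", "adj_SS"] == pytest.approx(acc, rel=1e-10)

    def test_ss_decompositions_are_consistent(self, design, rng):
        y = generate_rsm_responses(random_surface(4), design, 0.5, 9)
        t = anova_quadratic(design, y).set_index("source")
        assert t.loc["Error", "adj_SS"] == pytest.approx(
            t.loc["Lack of Fit", "adj_SS"] + t.loc["Pure Error", "adj_SS"])
        assert t.loc["Total", "adj_SS"] == pytest.approx(
            t.loc["Model", "adj_SS"] + t.loc["Error", "adj_SS"])

    @pytest.mark.parametrize("n_center", range(2, 9))
    def test_df_identities_hold_for_any_center_count(self, n_center):
        design = generate_ccd(n_center=n_center, seed=None)
        y = generate_rsm_responses(random_surface(5), design, 0.2,
                                   seed=n_center)
        t = anova_quadratic(design, y).set_index("source")
        n = design.n_runs
        assert t.loc["Total", "df"] == n - 1
        assert t.loc["Error", "df"] == (n - 1) - 20
        assert t.loc["Pure Error", "df"] == n_center - 1
        assert t.loc["Lack of Fit", "df"] == \
            t.loc["Error", "df"] - t.loc["Pure Error", "df"]

    def test_term_f_values_match_statsmodels_type3(self, design):
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm
        y = generate_rsm_responses(random_surface(6), design, 0.5, 3)
        frame = pd.DataFrame(design.uncoded, columns=list("abcde"))
        frame["y"] = y
        terms = (["a", "b", "c", "d", "e"]
                 + [f"I({v}**2)" for v in "abcde"]
                 + [f"{u}:{v}" for i, u in enumerate("abcde")
                    for v in "abcde"[i + 1:]])
        fit = smf.ols("y ~ " + " + ".join(terms), data=frame).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        ours = anova_quadratic(design, y).set_index("source")
        name_map = {"a": "X1", "b": "X2", "c": "X3", "d": "X4", "e": "X5"}
        for sm_name, our_name in name_map.items():
            assert ours.loc[our_name, "F"] == pytest.approx(
                ref.loc[sm_name, "F"], rel=1e-6)
        assert ours.loc["X1*X3", "F"] == pytest.approx(ref.loc["a:c", "F"],
                                                       rel=1e-6)


class TestEvaluateAndContour:
    def test_published_surface_at_the_origin(self):
        assert evaluate_surface(preset_surface(), [0, 0, 0, 0, 0]) == \
            pytest.approx(59.0)

    def test_published_surface_one_unit_of_lecithin(self):
        # intercept + linear X1 + quadratic X1^2 = 59.0 + 1.52 - 0.052
        assert evaluate_surface(preset_surface(), [1, 0, 0, 0, 0]) == \
            pytest.approx(60.468, abs=1e-12)

    def test_pure_interaction_is_symmetric_in_its_factors(self):
        surface = QuadraticSurface(0.0, np.zeros(5), np.zeros(5),
                                   [1.0] + [0.0] * 9)  # only the X1*X2 term
        assert evaluate_surface(surface, [3, 7, 0, 0, 0]) == 21.0
        assert evaluate_surface(surface, [7, 3, 0, 0, 0]) == 21.0

    def test_constant_surface_contours_flat(self):
        surface = QuadraticSurface(5.0, np.zeros(5), np.zeros(5), np.zeros(10))
        _, _, grid = contour_grid(surface, ("X1", "X3"),
                                  {"X2": 1.78, "X4": 19.5, "X5": 75.0},
                                  grid_n=11)
        assert np.allclose(grid, 5.0)

    def test_grid_matches_pointwise_evaluation(self):
        surface = preset_surface()
        factors = preset_factors()
        xs, ys, grid = contour_grid(surface, ("X1", "X3"),
                                    {"X2": 1.78, "X4": 19.5, "X5": 75.0},
                                    factors, grid_n=7)
        point = dict(zip([f.name for f in factors],
                         [np.nan, 1.78, np.nan, 19.5, 75.0]))
        for i in range(7):
            for j in range(7):
                point["X1"], point["X3"] = xs[j], ys[i]
                want = evaluate_surface(surface,
                                        [point[f.name] for f in factors])
                assert grid[i, j] == pytest.approx(want, abs=1e-12)

    def test_published_surface_grid_is_finite_everywhere(self):
        _, _, grid = contour_grid(preset_surface(), ("X1", "X3"),
                                  {"X2": 1.78, "X4": 19.5, "X5": 75.0},
                                  grid_n=31)
        assert np.all(np.isfinite(grid))
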
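"""Density model: table preparation, penalized fit oracles, prediction."""

import numpy as np
import pandas as pd
import pytest

from resfish.gamm import (EstimationError, FishDensityGAMM, ModelSpec,
                          prepare_model_table)


def _linked(rows):
    return pd.DataFrame(rows, columns=["reservoir_id", "year_sampled",
                                       "reservoir_age",
                                       "corrected_density_kg_ha"])


def _assign(pairs):
    return pd.DataFrame(pairs, columns=["reservoir_id", "class_label"])


class TestPrepare:
    def test_min_class_threshold(self):
        rows = [(f"A{i}", 1960, 10, 100.0) for i in range(4)] \
            + [(f"B{i}", 1960, 10, 100.0) for i in range(5)]
        linked = _linked(rows)
        asg = _assign([(r, "small" if r.startswith("A") else "big")
                       for r, *_ in rows])
        table, report = prepare_model_table(linked, asg)
        assert set(table["class_label"]) == {"big"}
        assert report["dropped_classes"] == ["small"]
        assert report["small_class_rows"] == 4

    def test_pass_through_when_clean(self):
        rows = [(f"R{i}", 1960 + i, 10 + i, 50.0 + i) for i in range(6)]
        linked = _linked(rows)
        table, report = prepare_model_table(linked, _assign(
            [(f"R{i}", "all") for i in range(6)]))
        assert len(table) == 6
        assert report["rows_out"] == report["rows_in"]

    def test_hand_enumerated_exclusions(self):
        """12 rows: 1 missing age, 1 zero density, one 3-row class -> 7 keep."""
        rows = []
        for i in range(9):
            rows.append((f"K{i}", 1960, 10, 100.0))  # class kept
        rows.append(("K9", 1960, np.nan, 100.0))     # missing age
        rows.append(("K10", 1960, 10, 0.0))          # zero density
        for i in range(1):
            pass
        rows.append(("T0", 1960, 10, 100.0))         # tiny class, 1 row
        linked = _linked(rows)
        asg = _assign([(f"K{i}", "keep") for i in range(11)]
                      + [("T0", "tiny")])
        spec = ModelSpec(min_class_n=5)
        table, report = prepare_model_table(linked, asg, spec)
        assert len(table) == 9
        assert report["missing_age"] == 1
        assert report["nonpositive_density"] == 1
        assert report["dropped_classes"] == ["tiny"]

    def test_empty_result_raises(self):
        linked = _linked([("R0", 1960, 10, -1.0)])
        with pytest.raises(EstimationError):
            prepare_model_table(linked, _assign([("R0", "all")]))


def _table(reservoir, age, year, density, label="all"):
    return pd.DataFrame({"reservoir_id": reservoir, "class_label": label,
                         "age": age, "year": year, "density": density})


class TestFit:
    def test_constant_response_shrinks_to_intercept(self):
        rng = np.random.default_rng(0)
        n = 120
        tbl = _table([f"R{i % 30}" for i in range(n)],
                     rng.uniform(0, 40, n), rng.uniform(1950, 1978, n),
                     50.0 * np.exp(rng.normal(0, 1e-4, n)))
        fit = FishDensityGAMM(tbl, ModelSpec()).fit()
        pred = fit.predict("all", 1978, age=20.0)
        assert pred == pytest.approx(50.0, rel=1e-3)
        assert fit.edf["age:all"] < 1.1
        assert fit.edf["year"] < 1.1

    def test_sine_age_curve_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        age = rng.uniform(0, 40, n)
        true_log_mu = 1.0 + 0.5 * np.sin(age / 8.0)
        shape = 50.0
        y = np.exp(true_log_mu) * rng.gamma(shape, 1 / shape, n)
        tbl = _table([f"R{i}" for i in range(n)], age,
                     np.full(n, 1960.0), y)
        spec = ModelSpec(include_random=False, include_year_smooth=False)
        fit = FishDensityGAMM(tbl, spec).fit()
        grid = np.linspace(1, 39, 50)
        pred_log = np.log([fit.predict("all", 1960, age=a) for a in grid])
        rmse = np.sqrt(np.mean((pred_log - (1 + 0.5 * np.sin(grid / 8))) ** 2))
        assert rmse < 0.1

    def test_penalty_limit_matches_glm_oracle(self):
        """With lambda -> infinity the smooths collapse to their linear null
        space; fitted values must match an independent Gamma-GLM fit of the
        linear-only respecification (statsmodels IRLS)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 300
        age = rng.uniform(0, 40, n)
        year = rng.uniform(1950, 1978, n)
        cls = rng.choice(["a", "b"], n)
        eta = 3.0 + 0.02 * age + (cls == "b") * (0.5 - 0.01 * age) \
            - 0.005 * (year - 1950)
        y = np.exp(eta) * rng.gamma(30, 1 / 30, n)
        tbl = _table([f"R{i}" for i in range(n)], age, year, y, label=cls)
        spec = ModelSpec(include_random=False)
        model = FishDensityGAMM(tbl, spec)
        fit = model.fit(lambdas={"age": 1e9, "year": 1e9})
        eta_hat = model.X @ fit.beta

        x_oracle = np.column_stack([
            np.ones(n), (cls == "b").astype(float),
            age * (cls == "a"), age * (cls == "b"), year])
        glm = sm.GLM(y, x_oracle,
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        assert np.max(np.abs(eta_hat - glm.predict(linear=True))) < 1e-4

    def test_nonpositive_density_rejected(self):
        tbl = _table(["R0", "R1"], [1, 2], [1960, 1961], [1.0, 0.0])
        with pytest.raises(EstimationError):
            FishDensityGAMM(tbl, ModelSpec())


class TestPredict:
    @pytest.fixture(scope="class")
    def flat_fit(self):
        rng = np.random.default_rng(3)
        n = 80
        tbl = _table([f"R{i % 20}" for i in range(n)],
                     rng.uniform(0, 40, n), rng.uniform(1950, 1978, n),
                     50.0 * np.exp(rng.normal(0, 1e-5, n)))
        return FishDensityGAMM(tbl, ModelSpec()).fit()

    def test_positive_everywhere(self, flat_fit):
        for year in (1950, 1978, 1993):
            assert flat_fit.predict("all", year, age=10.0) > 0

    def test_intercept_only_level(self, flat_fit):
        assert flat_fit.predict("all", 1993, age=5.0) \
            == pytest.approx(50.0, rel=1e-3)

    def test_unknown_class_rejected(self, flat_fit):
        with pytest.raises(KeyError):
            flat_fit.predict("nope", 1960, age=1.0)

    def test_continuity_across_extrapolation_boundary(self, recovery_design):
        """Predictions move smoothly from the last survey year into the
        standardization window (linear continuation, no jump)."""
        fit = recovery_design["fit"]
        cls = fit.model.classes[0]
        years = np.array([1977.0, 1978.0, 1979.0, 1985.0, 1993.0])
        preds = np.array([fit.predict(cls, y, age=30.0) for y in years])
        steps = np.abs(np.diff(np.log(preds)))
        assert steps[1] < max(3 * steps[0] + 1e-3, 0.1)
        assert np.all(preds > 0)

    def test_hand_built_linear_predictor(self, flat_fit):
        model = flat_fit.model
        row = model.design_row("all", 12.0, 1970.0, None)
        assert flat_fit.predict("all", 1970, age=12.0) \
            == pytest.approx(float(np.exp(row @ flat_fit.beta)))


class TestClassMeans:
    def test_two_reservoir_average(self):
        """Class mean is the arithmetic mean of per-reservoir predictions."""
        rng = np.random.default_rng(4)
        rows = []
        for rid, level in (("A", 40.0), ("B", 60.0)):
            for j in range(10):
                rows.append((rid, 1950 + 3 * j, 10 + 3 * j,
                             level * np.exp(rng.normal(0, 1e-5))))
        tbl = _table(*map(list, zip(*rows)))
        fit = FishDensityGAMM(tbl, ModelSpec()).fit()
        pa = fit.predict("all", 1993, reservoir_id="A")
        pb = fit.predict("all", 1993, reservoir_id="B")
        cm = fit.class_mean_density(1993)["all"]
        assert cm == pytest.approx((pa + pb) / 2, rel=1e-10)

    def test_recovery_on_reference_design(self, recovery_design):
        """Class-mean densities at 1993 within 10% of the generator truth;
        random-intercept sd within 25%."""
        fit = recovery_design["fit"]
        truth = recovery_design["truth"]
        m = fit.model
        for c, est in fit.class_mean_density(1993).items():
            rids = [r for r, cl in m.class_of_reservoir.items() if cl == c]
            true_mean = truth.loc[rids, "density_1993"].mean()
            assert abs(est / true_mean - 1) < 0.10
        assert abs(fit.random_intercept_sd() / 0.3 - 1) < 0.25

    def test_deviance_explained_in_unit_interval(self, recovery_design):
        fit = recovery_design["fit"]
        assert 0.0 <= fit.deviance_explained <= 1.0
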
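"""Risk-model forests, partial dependence, and safe-zone extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traj2targets.targets import (
    CLINICAL_FEATURES,
    PDProfile,
    RiskModelSpec,
    TargetsError,
    extract_safe_zone,
    jaccard,
    partial_dependence,
    pd_surface,
    safe_zone_report,
    train_rf,
)

SMALL_SPEC = RiskModelSpec(
    n_estimators=(60,), min_samples_leaf=(10,), max_features=("sqrt",), seed=0
)


def _cohort(rng, n=400, signal=None):
    df = pd.DataFrame(
        {
            "age": rng.uniform(30, 90, n),
            "sex": rng.integers(0, 2, n),
            "sofa": rng.integers(0, 20, n),
            "aps_iii": rng.uniform(20, 100, n),
            "invasive_vent": rng.integers(0, 2, n),
            "crrt": rng.integers(0, 2, n),
            "rrt": rng.integers(0, 2, n),
            "gas": rng.normal(0, 1, n),
        }
    )
    if signal == "threshold":
        df["event_icu"] = (df["gas"] > 0.3).astype(int)
    elif signal == "ushape":
        p = 1 / (1 + np.exp(-(-1.2 + 2.5 * np.clip(np.abs(df["gas"]) - 1, 0, None))))
        df["event_icu"] = (rng.random(n) < p).astype(int)
    else:
        df["event_icu"] = rng.integers(0, 2, n)
    return df


class _ConstantModel:
    feature_names_ = list(CLINICAL_FEATURES) + ["gas"]

    def __init__(self, c):
        self.c = c

    def predict_proba(self, X):
        p = np.full(len(X), self.c)
        return np.column_stack([1 - p, p])


class _StumpModel:
    """Splits only on the gas column at a fixed threshold."""

    feature_names_ = list(CLINICAL_FEATURES) + ["gas"]

    def __init__(self, s, p_left, p_right):
        self.s, self.p_left, self.p_right = s, p_left, p_right

    def predict_proba(self, X):
        p = np.where(X[:, -1] <= self.s, self.p_left, self.p_right)
        return np.column_stack([1 - p, p])


class TestTrainRF:
    def test_null_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(1)
        _, rep = train_rf(_cohort(rng), "gas", SMALL_SPEC)
        assert 0.40 <= rep["cv_auc"] <= 0.60

    def test_separable_outcome_gives_high_auc(self):
        rng = np.random.default_rng(2)
        _, rep = train_rf(_cohort(rng, signal="threshold"), "gas", SMALL_SPEC)
        assert rep["cv_auc"] >= 0.95

    def test_same_seed_same_model(self):
        rng = np.random.default_rng(3)
        df = _cohort(rng, signal="ushape")
        m1, r1 = train_rf(df, "gas", SMALL_SPEC)
        m2, r2 = train_rf(df, "gas", SMALL_SPEC)
        assert r1["best"] == r2["best"]
        X = df[m1.feature_names_].to_numpy()
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(4)
        df = _cohort(rng)
        df["event_icu"] = 1
        with pytest.raises(TargetsError):
            train_rf(df, "gas", SMALL_SPEC)

    def test_too_few_records_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(TargetsError):
            train_rf(_cohort(rng, n=20), "gas", SMALL_SPEC)


class TestPartialDependence:
    def test_constant_model_gives_constant_pd(self):
        rng = np.random.default_rng(6)
        prof = partial_dependence(_ConstantModel(0.37), _cohort(rng), "gas")
        assert np.allclose(prof.values, 0.37)

    def test_stump_model_matches_step_function(self):
        rng = np.random.default_rng(7)
        model = _StumpModel(s=0.1, p_left=0.2, p_right=0.7)
        grid = np.linspace(-2, 2, 41)
        prof = partial_dependence(model, _cohort(rng), "gas", grid=grid)
        expected = np.where(grid <= 0.1, 0.2, 0.7)
        assert np.allclose(prof.values, expected)

    def test_irrelevant_feature_gives_flat_pd(self):
        """A forest that never splits on the parameter yields constant PD."""
        rng = np.random.default_rng(8)
        df = _cohort(rng)
        df["event_icu"] = (df["age"] > 60).astype(int)  # driven by age only
        from sklearn.tree import DecisionTreeClassifier

        class _TreeWrap:
            feature_names_ = list(CLINICAL_FEATURES) + ["gas"]

            def __init__(self, t):
                self.t = t

            def predict_proba(self, X):
                return self.t.predict_proba(X)

        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(
            df[_TreeWrap.feature_names_], df["event_icu"]
        )
        prof = partial_dependence(_TreeWrap(tree), df, "gas")
        assert np.ptp(prof.values) == 0.0

    def test_pd_values_bounded(self):
        rng = np.random.default_rng(9)
        df = _cohort(rng, signal="ushape")
        model, _ = train_rf(df, "gas", SMALL_SPEC)
        prof = partial_dependence(model, df, "gas")
        assert (prof.values >= 0).all() and (prof.values <= 1).all()

    def test_additive_surface_properties(self):
        """For a model additive in the two features the surface equals the sum
        of univariate effects up to a constant, and marginalizing it over the
        second feature's empirical distribution reproduces the univariate PD."""

        class _Additive:
            feature_names_ = list(CLINICAL_FEATURES) + ["gas"]
            _i_age = feature_names_.index("age")

            def predict_proba(self, X):
                p = 0.2 + 0.003 * X[:, self._i_age] + 0.05 * np.abs(X[:, -1])
                p = np.clip(p, 0, 1)
                return np.column_stack([1 - p, p])

        rng = np.random.default_rng(10)
        df = _cohort(rng)
        model = _Additive()
        grid_x = np.linspace(-1.5, 1.5, 7)
        grid_y = np.linspace(35, 85, 9)
        prof = partial_dependence(model, df, "gas", grid=grid_x)
        surface = pd_surface(model, df, "gas", "age", grid_x, grid_y)
        # additivity: PD(x, y) - PD(x, y') independent of x
        col_diff = surface - surface[:, [0]]
        assert np.allclose(col_diff, col_diff[0][None, :], atol=1e-12)
        # marginalizing over the subjects' own ages reproduces the 1-D PD
        ages = df["age"].to_numpy()
        surf_at_ages = pd_surface(model, df, "gas", "age", grid_x, ages)
        assert np.allclose(surf_at_ages.mean(axis=1), prof.values, atol=1e-10)


class TestSafeZone:
    def test_v_shape_with_delta_zero_is_the_minimizer_point(self):
        grid = np.linspace(0, 10, 21)
        prof = PDProfile("p", grid, np.abs(grid - 4.0) / 10 + 0.1)
        z = extract_safe_zone(prof, delta=0.0)
        assert z.lo == z.hi == 4.0

    def test_monotone_decreasing_abuts_upper_bound(self):
        grid = np.linspace(0, 1, 11)
        prof = PDProfile("p", grid, np.linspace(0.9, 0.1, 11))
        z = extract_safe_zone(prof, delta=0.2)
        assert z.hi == grid[-1]

    def test_flat_profile_full_span_with_warning(self):
        grid = np.linspace(0, 1, 5)
        prof = PDProfile("p", grid, np.full(5, 0.3))
        with pytest.warns(UserWarning, match="flat"):
            z = extract_safe_zone(prof)
        assert (z.lo, z.hi) == (0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zone_contains_minimizer_and_widens_with_delta(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, 30)
        vals = np.clip(rng.random(30), 0.01, 0.99)
        prof = PDProfile("p", grid, vals)
        xmin = grid[np.argmin(vals)]
        prev_width = -1.0
        for delta in (0.0, 0.1, 0.3, 0.6, 1.0):
            z = extract_safe_zone(prof, delta=delta)
            assert z.lo <= xmin <= z.hi
            assert z.width >= prev_width
            prev_width = z.width

    def test_format_matches_interval_style(self):
        from traj2targets.targets import SafeZone

        z = SafeZone("pH", 7.32, 7.64, 0.2, 0.1, 0.1, 0.1, 0.5)
        assert z.format() == "pH 7.32–7.64"
        z2 = SafeZone("PO2", 25.0, 324.32, 0.2, 0.1, 0.1, 0.1, 0.5)
        assert z2.format() == "PO2 25.00–324.32 mmHg"


class TestReportRoundTrip:
    def test_six_parameters_six_rows_and_lossless_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        zones = {}
        profiles = {}
        for i, name in enumerate(
            ("pH", "PO2", "PCO2", "lactate", "base_excess", "total_co2")
        ):
            grid = np.linspace(0, 1, 25) + i
            vals = np.clip(0.2 + 0.5 * np.abs(grid - grid.mean()), 0, 1)
            profiles[name] = PDProfile(name, grid, vals)
            zones[name] = extract_safe_zone(profiles[name])
        table = safe_zone_report(zones, n_used=123)
        assert len(table) == 6
        path = tmp_path / "zones.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert np.allclose(back["lo"], table["lo"]) and np.allclose(back["hi"], table["hi"])
        # zones recomputed from the saved PD profiles match the report
        prof_path = tmp_path / "profiles.csv"
        pd.DataFrame(
            [
                {"parameter": n, "x": x, "pd": v}
                for n, p in profiles.items()
                for x, v in zip(p.grid, p.values)
            ]
        ).to_csv(prof_path, index=False)
        loaded = pd.read_csv(prof_path)
        for name in zones:
            sub = loaded[loaded.parameter == name]
            z = extract_safe_zone(PDProfile(name, sub["x"].to_numpy(), sub["pd"].to_numpy()))
            row = table.set_index("parameter").loc[name]
            assert z.lo == pytest.approx(row["lo"]) and z.hi == pytest.approx(row["hi"])


def test_jaccard_basics():
    assert jaccard((0, 1), (0, 1)) == 1.0
    assert jaccard((0, 1), (2, 3)) == 0.0
    assert jaccard((0, 2), (1, 3)) == pytest.approx(1 / 3)
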
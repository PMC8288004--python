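"""Generalized dissimilarity modelling: I-splines, fitting, elimination,
deviance partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from adaptscape.gdm import (GEO, SitePairTable, backward_eliminate,
                            build_pair_table, fit_gdm, haversine_km,
                            importance, ispline_basis, partition_deviance)


# ---------------------------------------------------------------- geometry
def test_haversine_one_degree_at_equator():
    assert haversine_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.5)


def test_build_pair_table_counts_and_distances():
    fst = pd.DataFrame(np.array([[0, .1, .2, .3], [.1, 0, .4, .5],
                                 [.2, .4, 0, .6], [.3, .5, .6, 0]]),
                       index=list("ABCD"), columns=list("ABCD"))
    preds = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]}, index=list("ABCD"))
    coords = pd.DataFrame({"lon": [0.0, 0.0, 1.0, 1.0],
                           "lat": [0.0, 1.0, 0.0, 1.0]}, index=list("ABCD"))
    pt = build_pair_table(fst, preds, coords)
    assert pt.n_pairs == 6
    row = pt.pairs.set_index(["site_i", "site_j"])
    assert row.loc[("A", "C"), "distance_km"] == pytest.approx(111.19, abs=0.5)


def test_coincident_sites_zero_distance():
    fst = pd.DataFrame([[0, .1], [.1, 0]], index=list("AB"), columns=list("AB"))
    preds = pd.DataFrame({"v": [1.0, 2.0]}, index=list("AB"))
    coords = pd.DataFrame({"lon": [5.0, 5.0], "lat": [-3.0, -3.0]},
                          index=list("AB"))
    pt = build_pair_table(fst, preds, coords)
    assert pt.pairs["distance_km"].iloc[0] == 0.0


from oracles import mspline_numeric as _mspline_numeric

# ----------------------------------------------------------------- I-splines


class TestISpline:
    def test_extremes(self):
        basis = ispline_basis([0.0, 1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(basis.evaluate(0.0), [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(basis.evaluate(4.0), [1, 1, 1], atol=1e-12)

    def test_clamping_outside_range(self):
        basis = ispline_basis([0.0, 2.0, 5.0])
        np.testing.assert_allclose(basis.evaluate(-3.0), [0, 0, 0])
        np.testing.assert_allclose(basis.evaluate(99.0), [1, 1, 1])

    def test_integrates_numeric_msplines(self):
        """Each basis function is the integral of its order-2 M-spline."""
        t1, t2, t3 = 1.0, 2.5, 6.0
        basis = ispline_basis([t1, t2, t2, t3])  # percentiles: 1, 2.5, 6
        knot_seq = [t1, t1, t2, t3, t3]
        xs = np.linspace(t1, t3, 100)
        vals = basis.evaluate(xs)
        for i in range(3):
            numeric = [quad(lambda u: _mspline_numeric(knot_seq, i, 2, u),
                            t1, x, points=[t2], limit=200)[0] for x in xs]
            np.testing.assert_allclose(vals[:, i], numeric, atol=1e-6)

    def test_nondecreasing(self):
        basis = ispline_basis(np.random.default_rng(0).uniform(0, 10, 50))
        xs = np.linspace(-1, 11, 300)
        vals = basis.evaluate(xs)
        assert (np.diff(vals, axis=0) >= -1e-12).all()

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ispline_basis([1.0, 1.0, 1.0])


# ----------------------------------------------------------------- fitting
def _synthetic_table(n_sites=12, seed=0, predictors=("x", "y"), angles=None):
    rng = np.random.default_rng(seed)
    site_values = pd.DataFrame(
        {p: rng.uniform(0, 10, n_sites) for p in predictors},
        index=[f"S{i}" for i in range(n_sites)])
    coords = pd.DataFrame({"lon": rng.uniform(0, 2, n_sites),
                           "lat": rng.uniform(0, 2, n_sites)},
                          index=site_values.index)
    rows = []
    from itertools import combinations
    for a, b in combinations(site_values.index, 2):
        rows.append((a, b, 0.0, haversine_km(coords.loc[a, "lon"],
                                             coords.loc[a, "lat"],
                                             coords.loc[b, "lon"],
                                             coords.loc[b, "lat"])))
    pairs = pd.DataFrame(rows, columns=["site_i", "site_j", "d", "distance_km"])
    return SitePairTable(pairs=pairs, site_values=site_values, coords=coords)


def _plant_response(pt, coefs, intercept=0.2):
    """Generate d from a known GDM over the table's own bases."""
    from adaptscape.gdm import _build_bases, _design
    preds = list(coefs)
    basis = _build_bases(pt, preds)
    X = _design(pt, preds, basis)
    beta = np.concatenate([np.asarray(coefs[p], dtype=float) for p in preds])
    eta = intercept + X @ beta
    pt.pairs["d"] = 1.0 - np.exp(-eta)
    return basis


class TestFitGdm:
    def test_zero_coefficients_give_zero_dissimilarity(self):
        pt = _synthetic_table()
        pt.pairs["d"] = 0.0
        model = fit_gdm(pt, predictors=["x"])
        np.testing.assert_allclose(model.predict(pt), 0.0, atol=1e-6)

    def test_noiseless_self_consistency(self):
        """A known monotone model is recovered with >99% deviance explained
        and summed coefficients within 5%."""
        pt = _synthetic_table(seed=3)
        truth = {"x": [0.4, 0.3, 0.2], "y": [0.15, 0.1, 0.05]}
        _plant_response(pt, truth)
        model = fit_gdm(pt, predictors=["x", "y"])
        assert model.pct_explained > 99.0
        np.testing.assert_allclose(model.predict(pt), pt.pairs["d"], atol=1e-3)
        imp = importance(model)
        for p, c in truth.items():
            assert imp[p] == pytest.approx(sum(c), rel=0.05)

    def test_monotone_in_predictor_difference(self):
        pt = _synthetic_table(seed=4)
        _plant_response(pt, {"x": [0.5, 0.2, 0.1]})
        model = fit_gdm(pt, predictors=["x"])
        basis = model.basis["x"]
        diffs = np.linspace(0, 1, 50)
        # increasing the basis difference never decreases predicted d
        etas = model.intercept + diffs * model.coefs["x"].sum()
        assert (np.diff(1 - np.exp(-etas)) >= -1e-12).all()

    def test_nested_models_never_lose_explained_deviance(self):
        pt = _synthetic_table(seed=5)
        _plant_response(pt, {"x": [0.4, 0.2, 0.1]})
        small = fit_gdm(pt, predictors=["x"])
        big = fit_gdm(pt, predictors=["x", "y"])
        assert big.pct_explained >= small.pct_explained - 1e-6

    def test_predictions_stay_in_unit_interval(self):
        pt = _synthetic_table(seed=6)
        _plant_response(pt, {"x": [2.0, 2.0, 2.0]}, intercept=1.0)
        model = fit_gdm(pt, predictors=["x", "y", GEO])
        pred = model.predict(pt)
        assert ((pred >= 0) & (pred < 1)).all()


class TestBackwardElimination:
    def test_generating_predictor_retained_noise_dropped(self):
        kept, dropped = 0, 0
        for seed in range(5):
            pt = _synthetic_table(seed=10 + seed)
            _plant_response(pt, {"x": [0.5, 0.4, 0.3]})
            model = backward_eliminate(pt, predictors=["x", "y"], n_perm=100,
                                       seed=seed)
            if "x" in model.predictors:
                kept += 1
            if "y" not in model.predictors:
                dropped += 1
        assert kept == 5
        assert dropped >= 4

    def test_strong_predictor_p_value_bound(self):
        pt = _synthetic_table(seed=20)
        _plant_response(pt, {"x": [0.6, 0.4, 0.2]})
        model = backward_eliminate(pt, predictors=["x"], n_perm=500, seed=1)
        assert model.p_values["x"] <= 0.002

    def test_deterministic_under_seed(self):
        pt = _synthetic_table(seed=21)
        _plant_response(pt, {"x": [0.5, 0.3, 0.1], "y": [0.05, 0.0, 0.0]})
        m1 = backward_eliminate(pt, predictors=["x", "y"], n_perm=50, seed=3)
        m2 = backward_eliminate(pt, predictors=["x", "y"], n_perm=50, seed=3)
        assert m1.p_values == m2.p_values
        assert m1.predictors == m2.predictors


class TestImportance:
    def test_sum_and_absence(self):
        pt = _synthetic_table(seed=30)
        _plant_response(pt, {"x": [0.5, 0.3, 0.2]})
        model = fit_gdm(pt, predictors=["x"])
        imp = importance(model)
        assert imp["x"] == pytest.approx(model.coefs["x"].sum())
        assert "y" not in imp


class TestPartitionDeviance:
    def test_single_group_explains_everything(self):
        pt = _synthetic_table(seed=40)
        _plant_response(pt, {"x": [0.5, 0.3, 0.2]})
        table = partition_deviance(pt, {"temperature": ["x"]})
        assert table["pct_of_explained"].iloc[0] == pytest.approx(100.0)

    def test_components_sum_to_hundred(self):
        pt = _synthetic_table(seed=41, predictors=("x", "y", "z"))
        _plant_response(pt, {"x": [0.4, 0.2, 0.1], "y": [0.2, 0.1, 0.0]})
        table = partition_deviance(pt, {"a": ["x"], "b": ["y"], "c": ["z"]})
        assert table["pct_of_explained"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_predictors_have_small_joint_component(self):
        """On a design whose pair-level turnover columns are decorrelated by
        construction, the two predictors' unique components are positive and
        the joint component is small."""
        from itertools import combinations

        from adaptscape.gdm import _build_bases, _design

        n = 20
        x = np.linspace(0, 10, n)

        def make_table(yvals):
            sv = pd.DataFrame({"x": x, "y": yvals},
                              index=[f"S{i}" for i in range(n)])
            coords = pd.DataFrame({"lon": np.zeros(n), "lat": np.zeros(n)},
                                  index=sv.index)
            rows = [(a, b, 0.0, 1.0)
                    for a, b in combinations(sv.index, 2)]
            pairs = pd.DataFrame(rows, columns=["site_i", "site_j", "d",
                                                "distance_km"])
            return SitePairTable(pairs=pairs, site_values=sv, coords=coords)

        # choose the permutation of y that decorrelates the two predictors'
        # summed turnover columns across pairs (seeded, deterministic)
        rng = np.random.default_rng(1)
        best_y, best_c = rng.permutation(x), np.inf
        for _ in range(800):
            y = rng.permutation(x)
            pt = make_table(y)
            X = _design(pt, ["x", "y"], _build_bases(pt, ["x", "y"]))
            c = abs(np.corrcoef(X[:, :3].sum(1), X[:, 3:].sum(1))[0, 1])
            if c < best_c:
                best_y, best_c = y.copy(), c
        pt = make_table(best_y)
        _plant_response(pt, {"x": [0.08, 0.05, 0.03], "y": [0.08, 0.05, 0.03]},
                        intercept=0.02)
        table = partition_deviance(pt, {"a": ["x"], "b": ["y"]})
        by = table.set_index("component")["pct_of_explained"]
        assert by["a"] > 0 and by["b"] > 0
        assert abs(by["a&b"]) < 5.0
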
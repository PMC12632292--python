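"""Growth profiles, cluster metrics, Ward clustering, bilateral symmetry."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fetalsp.residualize import fit_growth_model
from fetalsp.trajectories import (GA_GRID, GA_MIDPOINTS, bilateral_symmetry,
                                  cluster_metrics, growth_profile,
                                  ward_cluster)


class _Poly:
    """Minimal fitted-model stand-in: a raw polynomial."""

    def __init__(self, *coefs):
        self.coefs = np.asarray(coefs, dtype=float)

    def predict(self, x):
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefs)


def test_grid_layout():
    assert GA_GRID[0] == 22.0 and GA_GRID[-1] == 32.0 and len(GA_GRID) == 101
    assert GA_MIDPOINTS[0] == pytest.approx(22.05)
    assert GA_MIDPOINTS[-1] == pytest.approx(31.95)
    assert len(GA_MIDPOINTS) == 100


def test_linear_model_has_constant_rate():
    prof = growth_profile(_Poly(1.0, 0.5))       # v = 1 + 0.5 GA
    expected = 100.0 * 0.5 / (1.0 + 0.5 * 22.0)
    np.testing.assert_allclose(prof.rate, expected, rtol=1e-9)
    assert prof.baseline == pytest.approx(12.0)


def test_constant_model_has_zero_rate():
    prof = growth_profile(_Poly(5.0))
    np.testing.assert_allclose(prof.rate, 0.0, atol=1e-12)


def test_nonpositive_baseline_rejected():
    with pytest.raises(ValueError):
        growth_profile(_Poly(-100.0, 1.0))


def test_auc_endpoint_identity_for_random_profiles(rng):
    for _ in range(200):
        c = rng.normal(0, 1.0, 3) * [1.0, 0.05, 0.01]
        c[0] = abs(c[0]) + 40.0               # keep curve positive
        prof = growth_profile(_Poly(*c))
        v = prof.values
        expected = 100.0 * (v[-1] - v[0]) / v[0]
        assert prof.auc == pytest.approx(expected, rel=1e-9)


def test_rate_curve_invariant_under_measure_rescaling(rng):
    ga = rng.uniform(22, 32, 50)
    y = 2.0 + 0.3 * (ga - 22.0) + rng.normal(0, 0.05, 50)
    m1 = fit_growth_model(ga, y)
    m2 = fit_growth_model(ga, 1000.0 * y)
    p1, p2 = growth_profile(m1), growth_profile(m2)
    np.testing.assert_allclose(p1.rate, p2.rate, rtol=1e-6)


def test_cluster_metrics_constant_rate():
    rate = np.full(100, 7.0)
    m = cluster_metrics(rate)
    assert m["auc"] == pytest.approx(70.0)
    assert m["growth_density"] == 0.0
    assert m["peak_time"] == pytest.approx(22.05)   # tie -> earliest
    assert m["peak_rate"] == 7.0


def test_cluster_metrics_zero_curve():
    m = cluster_metrics(np.zeros(100))
    assert m["peak_rate"] == 0.0 and m["auc"] == 0.0
    assert m["growth_density"] == 0.0 and m["peak_time"] == pytest.approx(22.05)


def test_cluster_metrics_peak_location():
    rate = np.zeros(100)
    rate[40] = 5.0
    m = cluster_metrics(rate)
    assert m["peak_time"] == pytest.approx(GA_MIDPOINTS[40])
    assert m["growth_density"] > 0.0


def test_cluster_metrics_rejects_bad_curves():
    with pytest.raises(ValueError):
        cluster_metrics(np.array([]))
    with pytest.raises(ValueError):
        cluster_metrics(np.zeros(57))


def _archetype_curves(rng, n_per=10, noise=0.0):
    t = np.linspace(0, 1, 100)
    shapes = [np.exp(-t * 3.0) * 20.0,
              np.full(100, 10.0),
              np.exp(t * 2.5) * 2.0]
    X, labels = [], []
    for k, s in enumerate(shapes):
        for _ in range(n_per):
            X.append(s + rng.normal(0, noise, 100))
            labels.append(k)
    return np.vstack(X), np.array(labels)


def test_ward_recovers_well_separated_archetypes(rng):
    X, truth = _archetype_curves(rng, noise=0.3)
    sol = ward_cluster(X)
    assert sol.k == 3
    assert adjusted_rand_score(truth, sol.labels) == 1.0
    assert sol.silhouette_by_k[3] > sol.silhouette_by_k[2]
    assert sol.silhouette_by_k[3] > sol.silhouette_by_k[4]


def test_ward_override_k(rng):
    X, _ = _archetype_curves(rng, noise=0.3)
    sol = ward_cluster(X, override_k=2)
    assert sol.k == 2 and sol.overridden
    assert len(np.unique(sol.labels)) == 2


def test_identical_profiles_flagged_degenerate():
    X = np.tile(np.linspace(1, 2, 100), (6, 1))
    sol = ward_cluster(X)
    assert sol.degenerate and sol.k == 1
    assert (sol.labels == 1).all()


def test_ward_validates_inputs(rng):
    X, _ = _archetype_curves(rng)
    with pytest.raises(ValueError):
        ward_cluster(X[:3])
    with pytest.raises(ValueError):
        ward_cluster(X, k_candidates=[1, 2])
    with pytest.raises(ValueError):
        ward_cluster(X, k_candidates=[40])


def test_cluster_mean_curves_average_members(rng):
    X, truth = _archetype_curves(rng, noise=0.2)
    sol = ward_cluster(X)
    for c in range(1, sol.k + 1):
        np.testing.assert_allclose(sol.mean_curves[c],
                                   X[sol.labels == c].mean(axis=0))


# ------------------------------------------------------------- symmetry

def _labels_df(mapping):
    return pd.DataFrame(
        [dict(region=r, hemisphere=h, cluster=c)
         for r, (cl, cr) in mapping.items() for h, c in (("L", cl), ("R", cr))])


def test_perfectly_mirrored_labels_give_identity_matrix():
    mapping = {f"r{i}": (1 + i % 3, 1 + i % 3) for i in range(9)}
    mat = bilateral_symmetry(_labels_df(mapping))
    np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)
    off = mat.to_numpy()[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, 0.0)


def test_fully_crossed_hemispheres():
    mapping = {f"r{i}": (1, 2) for i in range(17)}
    mat = bilateral_symmetry(_labels_df(mapping))
    assert mat.loc[1, 2] == pytest.approx(1.0)    # 17 pairs / 17 regions
    assert mat.loc[1, 1] == 0.0 and mat.loc[2, 2] == 0.0


def test_symmetry_matrix_matches_brute_force_enumeration():
    mapping = {"a": (1, 1), "b": (1, 2), "c": (2, 2), "d": (2, 1)}
    df = _labels_df(mapping)
    mat = bilateral_symmetry(df)
    for i in (1, 2):
        for j in (1, 2):
            pairs = sum(1 for cl, cr in mapping.values()
                        if cl == i and cr == j)
            contrib = sum(1 for cl, cr in mapping.values()
                          if i in (cl, cr) or j in (cl, cr))
            assert mat.loc[i, j] == pytest.approx(pairs / contrib)
    assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()


def test_symmetry_missing_hemisphere_rejected():
    df = _labels_df({"a": (1, 1)}).iloc[:1]
    with pytest.raises(ValueError):
        bilateral_symmetry(df)
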
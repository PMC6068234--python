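import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from tvp.errors import DataError, ParameterError
from tvp.integration import (
    discretize_metrics,
    hierarchical_clusters,
    merge_predictors,
    nonmetric_mds,
    variant_distance_matrix,
)


def test_discretize_strict_threshold():
    table = pd.DataFrame(
        {"ddg_max": [2.5, 1.79, 0.0], "flag": [True, False, True]},
        index=["v1", "v2", "v3"],
    )
    out = discretize_metrics(table, {"ddg_max": 1.79})
    assert list(out["ddg_max"]) == [1, 0, 0]  # exactly at threshold -> unaltered
    assert list(out["flag"]) == [1, 0, 1]


def test_discretize_missing_threshold():
    with pytest.raises(ParameterError, match="score"):
        discretize_metrics(pd.DataFrame({"score": [1.0]}), {})


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    st.floats(-5, 5),
    st.floats(0.01, 5),
)
def test_discretize_monotone_per_column(values, threshold, bump):
    """Raising a value never flips altered (1) back to unaltered (0)."""
    base = pd.DataFrame({"m": values})
    raised = base + bump
    lo = discretize_metrics(base, {"m": threshold})["m"]
    hi = discretize_metrics(raised, {"m": threshold})["m"]
    assert (hi >= lo).all()


def test_distance_matrix_identical_rows_and_symmetry():
    table = pd.DataFrame(
        {"a": [1, 1, 0], "b": [0.0, 0.0, 2.0]}, index=["x", "y", "z"]
    )
    d = variant_distance_matrix(table)
    assert d.loc["x", "y"] == pytest.approx(0.0)
    assert np.allclose(d.values, d.values.T)
    assert np.allclose(np.diag(d.values), 0.0)


def test_distance_single_flag_difference_is_standardized_unit():
    table = pd.DataFrame({"flag": [1, 0, 0, 1], "c": [1.0, 1.0, 1.0, 1.0]})
    d = variant_distance_matrix(table)
    expected = 1.0 / table["flag"].std(ddof=1)
    assert d.iloc[0, 1] == pytest.approx(expected)


def test_distance_triangle_inequality(rng):
    table = pd.DataFrame(rng.normal(size=(8, 5)))
    d = variant_distance_matrix(table).to_numpy()
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_distance_all_missing_row_named():
    table = pd.DataFrame(
        {"a": [1.0, np.nan], "b": [2.0, np.nan]}, index=["ok", "empty"]
    )
    with pytest.raises(DataError, match="empty"):
        variant_distance_matrix(table)


def test_mds_recovers_planar_configuration(rng):
    X = rng.normal(size=(12, 2)) * [3.0, 1.0]
    d = squareform(pdist(X))
    coords, stress = nonmetric_mds(d, k=2, seed=0)
    assert stress < 0.01
    # recovered distances correlate monotonically with the originals
    rec = pdist(coords)
    rho = pd.Series(pdist(X)).corr(pd.Series(rec), method="spearman")
    assert rho > 0.99


def test_mds_equilateral_triangle():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    coords, _ = nonmetric_mds(d, k=2, seed=0)
    sides = pdist(coords)
    assert np.ptp(sides) <= 1e-3


def test_mds_deterministic_given_seed(rng):
    d = squareform(pdist(rng.normal(size=(9, 3))))
    c1, s1 = nonmetric_mds(d, k=2, seed=7)
    c2, s2 = nonmetric_mds(d, k=2, seed=7)
    assert np.array_equal(c1, c2)
    assert s1 == s2


def test_mds_rejects_asymmetric_input():
    d = np.array([[0, 1, 2], [1, 0, 1], [99, 1, 0]], dtype=float)
    with pytest.raises(DataError):
        nonmetric_mds(d)


def test_hierarchical_two_separated_groups(rng):
    a = rng.normal(0, 0.1, size=(5, 3))
    b = rng.normal(10, 0.1, size=(4, 3))
    d = squareform(pdist(np.vstack([a, b])))
    labels = hierarchical_clusters(d, k=2)
    assert len(set(labels[:5])) == 1
    assert len(set(labels[5:])) == 1
    assert labels[0] != labels[-1]


def test_hierarchical_edge_ks(rng):
    d = squareform(pdist(rng.normal(size=(6, 2))))
    assert len(set(hierarchical_clusters(d, k=6))) == 6
    assert len(set(hierarchical_clusters(d, k=1))) == 1
    with pytest.raises(ParameterError):
        hierarchical_clusters(d, k=7)


def test_merge_predictors_join_and_errors():
    metrics = pd.DataFrame({"m": [1, 0]}, index=pd.Index(["A1G", "R2W"], name="variant"))
    preds = pd.DataFrame({"cadd": [10.0]}, index=pd.Index(["A1G"], name="variant"))
    merged = merge_predictors(metrics, preds)
    assert merged.loc["A1G", "cadd"] == 10.0
    assert np.isnan(merged.loc["R2W", "cadd"])

    with pytest.warns(UserWarning, match="dropped"):
        merge_predictors(
            metrics,
            pd.DataFrame({"cadd": [1.0, 2.0]}, index=["A1G", "Z9Z"]),
        )
    with pytest.raises(DataError, match="duplicate"):
        merge_predictors(
            metrics, pd.DataFrame({"cadd": [1.0, 2.0]}, index=["A1G", "A1G"])
        )
    with pytest.raises(DataError, match="overlap"):
        merge_predictors(metrics, pd.DataFrame({"cadd": [1.0]}, index=["Z9Z"]))
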
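import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import structure_from_coords
from tvp.dynamics import (
    CouplingClass,
    HighestDensityInterval,
    MonitorDefinition,
    PrincipalAxisBand,
    classify_coupling,
    compute_monitors,
    correlation_matrix,
    density_interval,
    fit_pca,
    flag_altered,
    line_band,
    project_frames,
    subsampled_t,
)
from tvp.errors import DegenerateFitError, ParameterError
from tvp.structure import Trajectory


def monitor_structure(A, B, C, D):
    s = structure_from_coords([A, B, C, D])
    defn = MonitorDefinition(a=("A", 1), b=("A", 2), c=("A", 3), d=("A", 4))
    traj = Trajectory(s, s.coords[None])
    return compute_monitors(traj, defn)


def test_monitor_distance_345():
    mon = monitor_structure((0, 0, 0), (3, 4, 0), (10, 0, 0), (10, 10, 0))
    assert mon.loc[0, "d1"] == pytest.approx(5.0)
    assert mon.loc[0, "d2"] == pytest.approx(10.0)


def test_monitor_angles_right_and_straight():
    # theta1: vertex A=(0,0,0), arms to C=(1,0,0) and D=(0,1,0) -> 90 deg
    mon = monitor_structure((0, 0, 0), (5, 5, 5), (1, 0, 0), (0, 1, 0))
    assert mon.loc[0, "theta1"] == pytest.approx(90.0)
    # collinear: vertex A with C and D on opposite sides -> 180 deg
    mon = monitor_structure((0, 0, 0), (5, 5, 5), (1, 0, 0), (-2, 0, 0))
    assert mon.loc[0, "theta1"] == pytest.approx(180.0)


def test_monitor_coincident_anchor_is_degenerate():
    with pytest.raises(DegenerateFitError):
        monitor_structure((0, 0, 0), (3, 4, 0), (0, 0, 0), (1, 1, 1))


def test_monitor_definition_validation():
    with pytest.raises(ParameterError):
        MonitorDefinition(a=("A", 1), b=("A", 1), c=("A", 3), d=("A", 4))
    with pytest.raises(ParameterError):
        MonitorDefinition(angle_triples=(("A", "B", "C"),) * 5 + (("A", "A", "B"),))


# ---------------------------------------------------------------------------
# PCA


def test_pca_single_direction_of_motion(rng):
    base = rng.normal(size=30)
    mode = rng.normal(size=30)
    mode /= np.linalg.norm(mode)
    X = base + np.linspace(-2, 2, 40)[:, None] * mode
    model = fit_pca(X)
    assert model.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-9)
    assert abs(model.components_[0] @ mode) == pytest.approx(1.0, abs=1e-9)


def test_projection_of_mean_is_zero_and_linear(rng):
    X = rng.normal(size=(50, 12))
    model = fit_pca(X)
    assert np.allclose(project_frames(model.mean_[None], model), 0.0, atol=1e-10)
    probe = model.mean_ + 2.0 * model.components_[0]
    scores = project_frames(probe[None], model, k=1)
    assert scores[0, 0] == pytest.approx(2.0)


def test_projection_matches_bruteforce(rng):
    X = rng.normal(size=(20, 9))
    model = fit_pca(X)
    Y = rng.normal(size=(5, 9))
    expected = (Y - model.mean_) @ model.components_.T
    assert np.allclose(project_frames(Y, model), expected, atol=1e-12)


def test_pca_recovers_known_diagonal_covariance(rng):
    var = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
    X = rng.normal(size=(5000, 6)) * np.sqrt(var)
    model = fit_pca(X)
    assert np.allclose(model.explained_variance_, var, rtol=0.10)
    # orthonormal components; variance decomposition closes
    G = model.components_ @ model.components_.T
    assert np.allclose(G, np.eye(6), atol=1e-8)
    total = np.var(X, axis=0, ddof=1).sum()
    assert model.explained_variance_.sum() == pytest.approx(total, rel=1e-6)


def test_pca_requires_two_frames():
    with pytest.raises(ParameterError):
        fit_pca(np.zeros((1, 6)))


def test_projection_k_too_large(rng):
    model = fit_pca(rng.normal(size=(10, 4)))
    with pytest.raises(ParameterError):
        project_frames(rng.normal(size=(2, 4)), model, k=10)


# ---------------------------------------------------------------------------
# envelopes


def test_density_interval_point_mass_and_full_mass():
    x = np.full(20, 3.14)
    hdi = density_interval(x, mass=0.75)
    assert hdi.low_ == hdi.high_ == pytest.approx(3.14)
    y = np.arange(25, dtype=float)
    full = density_interval(y, mass=1.0)
    assert (full.low_, full.high_) == (0.0, 24.0)


def test_density_interval_matches_exhaustive_scan(rng):
    x = rng.normal(size=800)
    hdi = density_interval(x, mass=0.75)
    xs = np.sort(x)
    m = int(np.ceil(0.75 * len(xs)))
    best = min(
        ((xs[i + m - 1] - xs[i], xs[i], xs[i + m - 1]) for i in range(len(xs) - m + 1)),
        key=lambda t: t[0],
    )
    assert (hdi.low_, hdi.high_) == (pytest.approx(best[1]), pytest.approx(best[2]))
    # covers at least the requested mass
    assert ((x >= hdi.low_) & (x <= hdi.high_)).mean() >= 0.75


def test_density_interval_normal_halfwidth(rng):
    x = rng.normal(size=100_000)
    hdi = density_interval(x, mass=0.75)
    z = stats.norm.ppf(0.875)  # symmetric densest 75% of N(0,1)
    assert (hdi.high_ - hdi.low_) / 2 == pytest.approx(z, abs=0.03)


def test_density_interval_needs_samples():
    with pytest.raises(ParameterError):
        density_interval(np.arange(5), mass=0.75)


def test_line_band_points_exactly_on_line(rng):
    t = rng.normal(size=50)
    X = np.column_stack([t, 2.0 * t + 1.0])
    band = line_band(X, mass=0.6)
    assert band.halfwidth_ == pytest.approx(0.0, abs=1e-9)
    assert abs(band.direction_ @ np.array([1.0, 2.0]) / np.sqrt(5)) == pytest.approx(1.0)


def test_line_band_contains_requested_mass(rng):
    X = rng.normal(size=(500, 2))
    band = line_band(X, mass=0.6)
    res = band.residual(X)
    assert ((res >= band.res_low_) & (res <= band.res_high_)).mean() >= 0.6


def test_line_band_isotropic_gaussian_halfwidth(rng):
    X = rng.normal(size=(100_000, 2))
    band = line_band(X, mass=0.6)
    z = stats.norm.ppf(0.8)  # densest 60% of residual N(0,1): half-width ~0.84
    assert band.halfwidth_ == pytest.approx(z, abs=0.03)


def test_line_band_degenerate_cloud():
    with pytest.raises(DegenerateFitError):
        line_band(np.zeros((20, 2)))


def test_flag_altered_boundary_is_closed(rng):
    hdi = density_interval(np.linspace(0, 1, 100), mass=0.75)
    inside = np.full(11, (hdi.low_ + hdi.high_) / 2)
    assert not flag_altered(inside, hdi)
    on_boundary = np.full(11, hdi.high_)
    assert not flag_altered(on_boundary, hdi)
    outside = np.full(11, hdi.high_ + 1e-9)
    assert flag_altered(outside, hdi)


def test_flag_altered_band_uses_median_residual(rng):
    X = rng.normal(size=(200, 2))
    band = line_band(X, mass=0.6)
    shifted = X + 10.0 * np.array([-band.direction_[1], band.direction_[0]])
    assert flag_altered(shifted, band)
    assert not flag_altered(X, band)


def test_reference_never_altered_at_full_mass(rng):
    scores = rng.normal(size=300)
    env = density_interval(scores, mass=1.0)
    assert not flag_altered(scores, env)


# ---------------------------------------------------------------------------
# time-series statistics


def test_subsampled_t_identical_series(rng):
    x = rng.normal(size=5000)
    for seed in (0, 1, 2):
        assert abs(subsampled_t(x, x.copy(), seed=seed)) < 0.3


def test_subsampled_t_unit_shift(rng):
    a = rng.normal(0, 1, 10_000)
    b = rng.normal(1, 1, 10_000)
    t = subsampled_t(a, b, n_sub=100, rounds=10, seed=3)
    # Welch t at n=100/100, delta=1, sigma=1 is about -7
    assert abs(abs(t) - 7.0) <= 1.5


def test_subsampled_t_deterministic_and_length_guard(rng):
    a, b = rng.normal(size=300), rng.normal(size=300)
    assert subsampled_t(a, b, seed=11) == subsampled_t(a, b, seed=11)
    with pytest.raises(ParameterError):
        subsampled_t(a[:50], b, n_sub=100)


def test_correlation_matrix_perfect_anticorrelation():
    df = pd.DataFrame({"x": [1, 2, 3], "y": [6, 5, 4]})
    res = correlation_matrix(df)
    assert res.rho.loc["x", "y"] == pytest.approx(-1.0)
    # single-pair family: adjusted equals raw
    assert res.p_adj.loc["x", "y"] == pytest.approx(res.p_raw.loc["x", "y"])


def test_bh_stepup_worked_triple():
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
    assert list(adj) == pytest.approx([0.03, 0.03, 0.04])


def test_correlation_constant_series_warns(rng):
    df = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
    with pytest.warns(UserWarning, match="constant"):
        res = correlation_matrix(df)
    assert np.isnan(res.rho.loc["x", "c"])


def test_classify_coupling_boundaries_exact():
    assert classify_coupling(-0.8) is CouplingClass.WT_LIKE
    assert classify_coupling(-0.5) is CouplingClass.WT_LIKE
    assert classify_coupling(-0.3) is CouplingClass.DIMINISHED
    assert classify_coupling(0.0) is CouplingClass.DIMINISHED
    assert classify_coupling(0.2) is CouplingClass.SIGN_ALTERED
    with pytest.raises(ParameterError):
        classify_coupling(1.5)
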
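import numpy as np
import pytest

from tvp.dynamics import compute_monitors, fit_pca
from tvp.errors import ParameterError
from tvp.integration import discretize_metrics
from tvp.stability import stability_calls
from tvp.synthetic import (
    BundleSpec,
    TrajectorySpec,
    default_monitors,
    make_bundle_structure,
    make_ddg_table,
    make_trajectory,
    make_variant_sites,
)
from tvp.variants import Variant, VariantLabel


def test_bundle_atom_count_and_helix_map():
    s = make_bundle_structure(BundleSpec(n_helices=2, residues_per_helix=10))
    assert s.n_atoms == 20
    assert s.helix_map == {"H1": (1, 10), "H2": (11, 20)}


def test_bundle_ideal_helix_geometry():
    s = make_bundle_structure(BundleSpec(n_helices=3, residues_per_helix=12))
    coords = s.coords
    for lo, hi in s.helix_map.values():
        seg = coords[lo - 1 : hi]
        consec = np.linalg.norm(np.diff(seg, axis=0), axis=1)
        assert np.abs(consec - 3.8).max() <= 0.1


def test_bundle_deterministic_given_seed():
    a = make_bundle_structure(BundleSpec(seed=5))
    b = make_bundle_structure(BundleSpec(seed=5))
    assert np.array_equal(a.coords, b.coords)
    assert [x.residue_name for x in a.atoms] == [x.residue_name for x in b.atoms]


def test_trajectory_zero_amplitude_zero_noise_is_static():
    s = make_bundle_structure(BundleSpec(n_helices=4, residues_per_helix=8))
    spec = TrajectorySpec(n_frames=5, amplitude=0.0, noise_sigma=0.0)
    traj = make_trajectory(s, spec, default_monitors(s))
    assert np.array_equal(traj.frames, np.broadcast_to(s.coords, traj.frames.shape))


def test_single_injected_mode_recovered_by_pca(rng):
    s = make_bundle_structure(BundleSpec(n_helices=4, residues_per_helix=8))
    mode = rng.normal(size=(s.n_atoms, 3))
    mode /= np.linalg.norm(mode)
    spec = TrajectorySpec(
        n_frames=200, noise_sigma=0.0, seed=4, injected_modes=((mode, 1.5),)
    )
    traj = make_trajectory(s, spec)
    model = fit_pca(traj.frames.reshape(traj.n_frames, -1))
    cos = abs(model.components_[0] @ mode.ravel())
    assert cos >= 0.99


def test_target_correlation_realized():
    s = make_bundle_structure(BundleSpec())
    mon = default_monitors(s)
    spec = TrajectorySpec(n_frames=2000, monitor_target_corr=-0.8, seed=12)
    traj = make_trajectory(s, spec, mon)
    assert -0.9 <= traj.metadata["realized_corr_pearson"] <= -0.7
    series = compute_monitors(traj, mon)
    rho = series["d1"].corr(series["theta1"], method="spearman")
    assert rho == pytest.approx(traj.metadata["realized_corr_spearman"])


def test_trajectory_deterministic_given_seed():
    s = make_bundle_structure(BundleSpec(n_helices=4, residues_per_helix=8))
    mon = default_monitors(s)
    spec = TrajectorySpec(n_frames=20, seed=9)
    a = make_trajectory(s, spec, mon)
    b = make_trajectory(s, spec, mon)
    assert np.array_equal(a.frames, b.frames)


def test_variant_sites_modes(medium_bundle):
    assert make_variant_sites(medium_bundle, 0) == []
    modeled = {r for (_, r) in medium_bundle.ca_residues()}
    uniform = make_variant_sites(medium_bundle, 10, "uniform", seed=1)
    assert len(uniform) == 10 and set(uniform) <= modeled
    clustered = make_variant_sites(medium_bundle, 10, "clustered", seed=1, radius=15.0)
    assert len(clustered) == 10 and set(clustered) <= modeled
    with pytest.raises(ParameterError):
        make_variant_sites(medium_bundle, 10_000)


def test_ddg_table_sigma_zero_hits_class_means():
    variants = [
        Variant("A", 1, "G", VariantLabel.BENIGN),
        Variant("R", 2, "W", VariantLabel.PATHOGENIC),
    ]
    records = make_ddg_table(variants, sigma=0.0, seed=0)
    by_var = {(r.variant, r.conformation.value): r.ddg for r in records}
    assert by_var[("A1G", "IF")] == 0.0 and by_var[("A1G", "OF")] == 0.0
    assert by_var[("R2W", "IF")] == 4.0 and by_var[("R2W", "OF")] == 4.0


def test_ddg_sample_mean_within_clt_bound():
    variants = [Variant("A", i, "G", VariantLabel.PATHOGENIC) for i in range(1, 41)]
    records = make_ddg_table(variants, sigma=1.0, seed=123)
    values = np.array([r.ddg for r in records])  # 80 draws
    assert abs(values.mean() - 4.0) <= 3.0 / np.sqrt(len(values))


def test_ddg_deterministic_and_missing_class_mean():
    variants = [Variant("A", 1, "G", VariantLabel.BENIGN)]
    a = make_ddg_table(variants, seed=3)
    b = make_ddg_table(variants, seed=3)
    assert a == b
    with pytest.raises(ParameterError):
        make_ddg_table(variants, class_means={"pathogenic": 4.0})


def test_pathogenic_variants_flagged_altered_across_seeds():
    """With pathogenic ddG mean 4 vs benign 0, at least 90% of synthetic
    pathogenic variants are altered in >= 1 discretized metric over 20 seeds."""
    flagged = total = 0
    for seed in range(20):
        variants = [
            Variant("A", i, "E", VariantLabel.PATHOGENIC) for i in range(1, 11)
        ]
        calls = stability_calls(make_ddg_table(variants, sigma=1.0, seed=seed))
        import pandas as pd

        table = pd.DataFrame(
            {"ddg_max": [c.ddg_max for c in calls]},
            index=[c.variant for c in calls],
        )
        disc = discretize_metrics(table, {"ddg_max": 1.79})
        flagged += int(disc["ddg_max"].sum())
        total += len(variants)
    assert flagged >= 0.9 * total
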
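"""A complete synthetic study scenario on disk, ready for the pipeline.

``make_scenario`` composes the generators into the file set the pipeline
consumes: a helical-bundle model, per-variant trajectories with class-typical
gate coupling and mode shifts, a variant table (pathogenic sites spatially
clustered), per-conformation ΔΔG tables, a channel-lining list, synthetic
genomics-predictor scores and a ready-to-run YAML configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.SeqUtils import seq1

from .channel import axis_lining
from .errors import ParameterError
from .structure import Conformation, Structure, write_structure, write_trajectory
from .dynamics import MonitorDefinition
from .stability import write_ddg_table
from .synthetic import (
    BundleSpec,
    TrajectorySpec,
    default_monitors,
    make_bundle_structure,
    make_ddg_table,
    make_trajectory,
    make_variant_sites,
)
from .variants import Variant, VariantLabel, write_variant_table

__all__ = ["ScenarioSpec", "make_scenario"]

_BENIGN_MUTS = "STVG"
_PATHOGENIC_MUTS = "KRDE"  # charge-altering, mirrors lining electrostatics


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for a synthetic scenario.

    Class sizes mirror the curated variant panel (4 benign, 10 pathogenic,
    9 VUS); trajectories are simulated in duplicate for the wild type plus a
    per-class subset, with wild-type-like coupling Cor(d1, θ1) = −0.8 for
    benign runs and diminished/sign-altered coupling plus a gate-mode shift
    for pathogenic runs.
    """

    seed: int = 0
    n_benign: int = 4
    n_pathogenic: int = 10
    n_vus: int = 9
    n_frames: int = 400
    n_replicates: int = 2
    dynamics_benign: int = 4
    dynamics_pathogenic: int = 4
    dynamics_vus: int = 3
    amplitude: float = 2.0
    noise_sigma: float = 0.3
    wt_corr: float = -0.8
    diminished_corr: float = -0.25
    sign_altered_corr: float = 0.3
    pathogenic_shift: float = 6.0  # Å along the gate distance mode
    cluster_radius: float = 15.0
    conformations: tuple[str, ...] = ("IF",)
    bundle: BundleSpec = BundleSpec()


def _pick_mut(rng: np.random.Generator, wt: str, pool: str) -> str:
    choices = [aa for aa in pool if aa != wt]
    return str(rng.choice(choices))


def _make_variants(
    structure: Structure, spec: ScenarioSpec, rng: np.random.Generator
) -> list[Variant]:
    taken: set[int] = set()

    def sample(n: int, mode: str, label: VariantLabel, pool: str) -> list[Variant]:
        out: list[Variant] = []
        attempts = 0
        while len(out) < n:
            sites = make_variant_sites(
                structure,
                n,
                mode=mode,
                seed=int(rng.integers(2**31)),
                radius=spec.cluster_radius,
            )
            for pos in sites:
                if pos in taken or len(out) >= n:
                    continue
                taken.add(pos)
                chain = structure.ca_residues()[0][0]
                wt = seq1(structure.residue_name_at(chain, pos))
                out.append(Variant(wt, pos, _pick_mut(rng, wt, pool), label))
            attempts += 1
            if attempts > 50:
                raise ParameterError("could not place disjoint variant sites")
        return out

    benign = sample(spec.n_benign, "uniform", VariantLabel.BENIGN, _BENIGN_MUTS)
    pathogenic = sample(
        spec.n_pathogenic, "clustered", VariantLabel.PATHOGENIC, _PATHOGENIC_MUTS
    )
    vus = sample(spec.n_vus, "uniform", VariantLabel.VUS, _BENIGN_MUTS + _PATHOGENIC_MUTS)
    return benign + pathogenic + vus


def _trajectory_plan(
    variants: Sequence[Variant], spec: ScenarioSpec
) -> list[tuple[str, float, float]]:
    """(name, target_corr, shift) for WT plus the dynamics subset."""
    plan = [("WT", spec.wt_corr, 0.0)]
    by_label = {
        lab: [v for v in variants if v.label == lab]
        for lab in (VariantLabel.BENIGN, VariantLabel.PATHOGENIC, VariantLabel.VUS)
    }
    for v in by_label[VariantLabel.BENIGN][: spec.dynamics_benign]:
        plan.append((str(v), spec.wt_corr, 0.0))
    for i, v in enumerate(by_label[VariantLabel.PATHOGENIC][: spec.dynamics_pathogenic]):
        corr = spec.diminished_corr if i % 2 == 0 else spec.sign_altered_corr
        plan.append((str(v), corr, spec.pathogenic_shift))
    for i, v in enumerate(by_label[VariantLabel.VUS][: spec.dynamics_vus]):
        if i == 0:  # one benign-like VUS
            plan.append((str(v), spec.wt_corr, 0.0))
        else:
            corr = spec.sign_altered_corr if i % 2 == 0 else spec.diminished_corr
            plan.append((str(v), corr, spec.pathogenic_shift))
    return plan


def _predictor_table(
    variants: Sequence[Variant], rng: np.random.Generator
) -> pd.DataFrame:
    """dbNSFP-style synthetic scores (CADD-like phred, SIFT-like damage prob)."""
    cadd_mu = {"benign": 8.0, "pathogenic": 28.0, "vus": 18.0}
    sift_mu = {"benign": 0.6, "pathogenic": 0.02, "vus": 0.25}
    rows = []
    for v in variants:
        lab = v.label.value
        rows.append(
            {
                "variant": str(v),
                "cadd_phred": float(np.clip(rng.normal(cadd_mu[lab], 4.0), 0, 60)),
                "sift_score": float(np.clip(rng.normal(sift_mu[lab], 0.1), 0, 1)),
            }
        )
    return pd.DataFrame(rows)


def make_scenario(out_dir: str | Path, spec: ScenarioSpec | None = None) -> dict:
    """Write a full synthetic scenario; returns a manifest of paths/objects."""
    spec = spec or ScenarioSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj_dir = out / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    structure = make_bundle_structure(spec.bundle)
    monitors = default_monitors(structure, spec.bundle.chain_id)
    variants = _make_variants(structure, spec, rng)

    structure_path = out / "structure_if.pdb"
    write_structure(structure, structure_path)
    helices_path = out / "helices.tsv"
    helices_path.write_text(
        "helix\tstart\tend\n"
        + "".join(
            f"{h}\t{lo}\t{hi}\n" for h, (lo, hi) in structure.helix_map.items()
        )
    )
    variants_path = out / "variants.tsv"
    write_variant_table(variants, variants_path)

    ddg_path = out / "ddg.tsv"
    write_ddg_table(
        make_ddg_table(variants, seed=int(rng.integers(2**31))), ddg_path
    )

    half = spec.bundle.n_helices // 2 or 1
    lining = axis_lining(
        structure,
        [f"H{i + 1}" for i in range(half)],
        [f"H{i + 1}" for i in range(half, spec.bundle.n_helices)],
        radius=12.0,
    )
    lining_path = out / "lining.tsv"
    lining_path.write_text(
        "# channel-lining residue positions (axis heuristic, synthetic)\n"
        + "".join(f"{p}\n" for p in sorted(lining.positions))
    )

    selection_path = out / "selection.tsv"
    selection_path.write_text(
        "".join(f"{c}\t{r}\n" for (c, r) in structure.ca_residues())
    )

    predictors_path = out / "predictors.tsv"
    _predictor_table(variants, rng).to_csv(predictors_path, sep="\t", index=False)

    manifest_rows = []
    for name, corr, shift in _trajectory_plan(variants, spec):
        for conf in spec.conformations:
            for rep in range(1, spec.n_replicates + 1):
                tspec = TrajectorySpec(
                    n_frames=spec.n_frames,
                    amplitude=spec.amplitude,
                    monitor_target_corr=corr,
                    noise_sigma=spec.noise_sigma,
                    shift=shift,
                    seed=int(rng.integers(2**31)),
                )
                traj = make_trajectory(structure, tspec, monitors)
                path = traj_dir / f"{name}_{conf}_r{rep}.pdb"
                write_trajectory(traj, path)
                manifest_rows.append(
                    {
                        "variant": name,
                        "conformation": conf,
                        "replicate": rep,
                        "path": str(path.relative_to(out)),
                        "target_corr": corr,
                        "realized_corr": traj.metadata["realized_corr_pearson"],
                    }
                )
    manifest_path = out / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)

    config = {
        "version": 1,
        "seed": spec.seed,
        "out_dir": "results",
        "paths": {
            "structure_if": structure_path.name,
            "helices": helices_path.name,
            "trajectories": manifest_path.name,
            "variants": variants_path.name,
            "ddg": ddg_path.name,
            "lining": lining_path.name,
            "predictors": predictors_path.name,
            "selection": selection_path.name,
        },
        "params": {
            "contact_threshold": 15.0,
            "n_perm": 999,
            "statistics": ["compactness", "density", "normalized_density"],
            "threshold_kbt": 3.0,
            "temperature": 300.0,
            "mass_1d": 0.75,
            "mass_2d": 0.60,
            "n_sub": 100,
            "rounds": 10,
            "n_components": 3,
            "hydropathy_cutoff": 2.0,
            "mds_k": 2,
            "n_clusters": 3,
        },
        "monitors": {
            lab.lower(): list(monitors.anchor(lab)) for lab in "ABCD"
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))

    return {
        "structure": structure,
        "monitors": monitors,
        "variants": variants,
        "lining": lining,
        "config": config_path,
        "out_dir": out,
    }
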
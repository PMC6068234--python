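"""Config-driven orchestration of the analysis stages.

Stages run in dependency order (cluster → channel → stability → dynamics →
integrate); each reads its declared inputs, writes TSV outputs with a
provenance header (stage, parameters, seeds, package version — no timestamps,
so reruns are byte-identical) and can also be run alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channel import read_lining, score_table, uncharged_reference
from .clustering import build_contact_graph, permutation_test
from .errors import ParameterError, PipelineError
from .structure import (
    Conformation,
    Selection,
    Structure,
    read_structure,
    read_trajectory,
    superpose_trajectory,
)
from .dynamics import (
    CartesianPCA,
    HighestDensityInterval,
    MonitorDefinition,
    PrincipalAxisBand,
    classify_coupling,
    compute_monitors,
    correlation_matrix,
    flag_altered,
    selection_matrix,
    subsampled_t,
)
from .stability import (
    calls_frame,
    compare_groups,
    kbt_threshold_kcal,
    read_ddg_table,
    stability_calls,
)
from .integration import (
    discretize_metrics,
    hierarchical_clusters,
    merge_predictors,
    nonmetric_mds,
    variant_distance_matrix,
)
from .variants import (
    Variant,
    VariantLabel,
    delta_property,
    load_default_properties,
    read_variant_table,
)

log = logging.getLogger(__name__)

STAGES = ("cluster", "channel", "stability", "dynamics", "integrate")

# fixed per-stage seed offsets keep stage seeds independent yet reproducible
_SEED_OFFSET = {"cluster": 11, "dynamics": 23, "integrate": 37}

DEFAULT_PARAMS: dict = {
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
}


@dataclass
class RunConfig:
    seed: int
    base_dir: Path
    out_dir: Path
    paths: dict[str, Path]
    params: dict
    monitors: MonitorDefinition | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent
        paths = {}
        for key, value in (raw.get("paths") or {}).items():
            if value is None:
                continue
            p = base / value
            if not p.exists():
                raise PipelineError(f"paths.{key}: file not found: {p}")
            paths[key] = p
        params = dict(DEFAULT_PARAMS)
        params.update(raw.get("params") or {})
        monitors = None
        if raw.get("monitors"):
            m = raw["monitors"]
            try:
                monitors = MonitorDefinition(
                    a=(str(m["a"][0]), int(m["a"][1])),
                    b=(str(m["b"][0]), int(m["b"][1])),
                    c=(str(m["c"][0]), int(m["c"][1])),
                    d=(str(m["d"][0]), int(m["d"][1])),
                    angle_triples=tuple(
                        tuple(t) for t in m.get(
                            "angle_triples",
                            MonitorDefinition.__dataclass_fields__[
                                "angle_triples"
                            ].default,
                        )
                    ),
                )
            except (KeyError, IndexError, TypeError) as exc:
                raise PipelineError(f"monitors: invalid specification ({exc})") from exc
        if "seed" not in raw:
            raise PipelineError("seed: required (every stochastic stage is seeded)")
        out_dir = base / raw.get("out_dir", "results")
        return cls(
            seed=int(raw["seed"]),
            base_dir=base,
            out_dir=out_dir,
            paths=paths,
            params=params,
            monitors=monitors,
        )

    def require(self, key: str, stage: str) -> Path:
        if key not in self.paths:
            raise PipelineError(f"stage {stage!r} requires paths.{key}")
        return self.paths[key]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSET.get(stage, 0)) % (2**31)


def _provenance(stage: str, cfg: RunConfig, extra: dict | None = None) -> str:
    items = {"tvp_version": __version__, "stage": stage, "seed": cfg.stage_seed(stage)}
    items.update(extra or {})
    return "".join(f"# {k}={items[k]}\n" for k in sorted(items))


def _write(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig,
           extra: dict | None = None, index: bool = False) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(stage, cfg, extra))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")
    return path


def _read_helix_map(path: Path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r["helix"]): (int(r["start"]), int(r["end"])) for _, r in df.iterrows()
    }


def _load_structure(cfg: RunConfig, key: str, conformation: Conformation) -> Structure:
    helix_map = (
        _read_helix_map(cfg.paths["helices"]) if "helices" in cfg.paths else None
    )
    return read_structure(cfg.require(key, "structure"), conformation, helix_map)


def _variants(cfg: RunConfig, stage: str) -> list[Variant]:
    return read_variant_table(cfg.require("variants", stage))


# ---------------------------------------------------------------------------
# stages


def stage_cluster(cfg: RunConfig) -> dict[str, Path]:
    structure = _load_structure(cfg, "structure_if", Conformation.IF)
    variants = _variants(cfg, "cluster")
    positions = sorted({v.position for v in variants})
    threshold = float(cfg.params["contact_threshold"])
    rows = []
    for i, stat in enumerate(cfg.params["statistics"]):
        res = permutation_test(
            structure,
            positions,
            statistic=stat,
            n_perm=int(cfg.params["n_perm"]),
            seed=cfg.stage_seed("cluster") + i,
            threshold=threshold,
        )
        rows.append(
            {"statistic": stat, "observed": res.observed, "p": res.p_value,
             "n_perm": res.n_perm}
        )
    graph = build_contact_graph(structure, positions, threshold)
    edges = pd.DataFrame(
        [
            {"residue_a": a, "residue_b": b, "distance": d["distance"]}
            for a, b, d in sorted(graph.edges(data=True))
        ]
    )
    extra = {"contact_threshold": threshold, "n_sites": len(positions)}
    return {
        "cluster_stats": _write(
            pd.DataFrame(rows), cfg.out_dir / "cluster_stats.tsv", "cluster", cfg, extra
        ),
        "cluster_edges": _write(
            edges, cfg.out_dir / "cluster_edges.tsv", "cluster", cfg, extra
        ),
    }


def stage_channel(cfg: RunConfig) -> dict[str, Path]:
    variants = _variants(cfg, "channel")
    lining = read_lining(cfg.require("lining", "channel"))
    props = load_default_properties()
    df = score_table(variants, lining, props)
    extra = {"uncharged_reference": round(df.attrs["uncharged_reference"], 6)}
    return {
        "channel_scores": _write(
            df, cfg.out_dir / "channel_scores.tsv", "channel", cfg, extra
        )
    }


def stage_stability(cfg: RunConfig) -> dict[str, Path]:
    records = read_ddg_table(cfg.require("ddg", "stability"))
    variants = _variants(cfg, "stability")
    calls = stability_calls(
        records,
        threshold_kbt=float(cfg.params["threshold_kbt"]),
        temperature=float(cfg.params["temperature"]),
    )
    labels = {str(v): v.label for v in variants}
    comparisons = []
    for column in ("ddg_max", "ddg_if", "ddg_of"):
        comparisons.append(compare_groups(calls, labels, column=column))
    extra = {
        "threshold_kcal": round(
            kbt_threshold_kcal(
                float(cfg.params["threshold_kbt"]), float(cfg.params["temperature"])
            ),
            6,
        )
    }
    return {
        "stability_calls": _write(
            calls_frame(calls), cfg.out_dir / "stability_calls.tsv", "stability",
            cfg, extra
        ),
        "stability_groups": _write(
            pd.concat(comparisons, ignore_index=True),
            cfg.out_dir / "stability_groups.tsv", "stability", cfg, extra
        ),
    }


def _benign_names(variants: Iterable[Variant]) -> set[str]:
    return {"WT"} | {str(v) for v in variants if v.label == VariantLabel.BENIGN}


def stage_dynamics(cfg: RunConfig) -> dict[str, Path]:
    manifest = pd.read_csv(cfg.require("trajectories", "dynamics"), sep="\t", comment="#")
    for col in ("variant", "conformation", "replicate", "path"):
        if col not in manifest.columns:
            raise PipelineError(f"trajectory manifest: missing column {col!r}")
    if cfg.monitors is None:
        raise PipelineError("stage 'dynamics' requires a monitors block")
    variants = _variants(cfg, "dynamics")
    benign = _benign_names(variants)
    references = {"IF": _load_structure(cfg, "structure_if", Conformation.IF)}
    if "structure_of" in cfg.paths:
        references["OF"] = _load_structure(cfg, "structure_of", Conformation.OF)
    selection = (
        Selection.from_tsv(cfg.paths["selection"])
        if "selection" in cfg.paths
        else None
    )
    n_pc = int(cfg.params["n_components"])
    mass_1d, mass_2d = float(cfg.params["mass_1d"]), float(cfg.params["mass_2d"])

    metric_rows, monitor_rows = [], []
    wt_corr_out = None
    for conf, group in manifest.groupby("conformation", sort=True):
        reference = references.get(conf, references["IF"])
        sel = selection or Selection(tuple(reference.ca_residues()))
        per_variant_frames: dict[str, list[np.ndarray]] = {}
        per_variant_monitors: dict[str, list[pd.DataFrame]] = {}
        for _, row in group.iterrows():
            path = cfg.base_dir / row["path"]
            if not path.exists():
                raise PipelineError(f"trajectory file not found: {path}")
            traj = read_trajectory(path, reference)
            traj = superpose_trajectory(traj, reference, sel)
            mon = compute_monitors(traj, cfg.monitors)
            mon.insert(0, "variant", row["variant"])
            mon.insert(1, "conformation", conf)
            mon.insert(2, "replicate", row["replicate"])
            monitor_rows.append(mon.reset_index())
            per_variant_frames.setdefault(row["variant"], []).append(
                selection_matrix(traj, sel)
            )
            per_variant_monitors.setdefault(row["variant"], []).append(mon)

        pooled_ref = np.vstack(
            [np.vstack(v) for k, v in per_variant_frames.items() if k in benign]
        )
        if pooled_ref.shape[0] < 2:
            raise PipelineError(
                f"{conf}: no wild-type/benign trajectories to fit the PCA reference"
            )
        pca = CartesianPCA(n_components=n_pc).fit(pooled_ref)
        ref_scores = pca.transform(pooled_ref)
        envelopes = [
            HighestDensityInterval(mass=mass_1d).fit(ref_scores[:, j])
            for j in range(n_pc)
        ]
        band = (
            PrincipalAxisBand(mass=mass_2d).fit(ref_scores[:, :2])
            if n_pc >= 2
            else None
        )
        wt_mon = (
            pd.concat(per_variant_monitors["WT"], ignore_index=True)
            if "WT" in per_variant_monitors
            else None
        )
        for name, mats in sorted(per_variant_frames.items()):
            scores = pca.transform(np.vstack(mats))
            mon = pd.concat(per_variant_monitors[name], ignore_index=True)
            rho = float(mon["d1"].corr(mon["theta1"], method="spearman"))
            row = {
                "variant": name,
                "conformation": conf,
                "n_frames": scores.shape[0],
                "cor_d1_theta1": rho,
                "coupling_class": classify_coupling(np.clip(rho, -1, 1)).value,
            }
            for j in range(n_pc):
                row[f"median_pc{j + 1}"] = float(np.median(scores[:, j]))
                row[f"altered_pc{j + 1}"] = flag_altered(scores[:, j], envelopes[j])
            if band is not None:
                row["altered_band_pc12"] = flag_altered(scores[:, :2], band)
            if wt_mon is not None and name != "WT":
                row["t_d1_vs_wt"] = subsampled_t(
                    mon["d1"],
                    wt_mon["d1"],
                    n_sub=min(
                        int(cfg.params["n_sub"]), len(mon), len(wt_mon)
                    ),
                    rounds=int(cfg.params["rounds"]),
                    seed=cfg.stage_seed("dynamics"),
                )
            metric_rows.append(row)
        if wt_mon is not None and conf == sorted(manifest["conformation"].unique())[0]:
            corr = correlation_matrix(
                wt_mon[["d1", "d2"] + [f"theta{k}" for k in range(1, 7)]]
            )
            wt_corr_out = (
                corr.rho.stack()
                .rename("rho")
                .to_frame()
                .join(corr.p_adj.stack().rename("p_adj"))
                .reset_index(names=["metric_a", "metric_b"])
            )

    extra = {"mass_1d": mass_1d, "mass_2d": mass_2d, "n_components": n_pc}
    out = {
        "dynamics_metrics": _write(
            pd.DataFrame(metric_rows), cfg.out_dir / "dynamics_metrics.tsv",
            "dynamics", cfg, extra
        ),
        "monitors": _write(
            pd.concat(monitor_rows, ignore_index=True),
            cfg.out_dir / "monitors.tsv", "dynamics", cfg, extra
        ),
    }
    if wt_corr_out is not None:
        out["wt_monitor_correlations"] = _write(
            wt_corr_out, cfg.out_dir / "wt_monitor_correlations.tsv",
            "dynamics", cfg, extra
        )
    return out


def _read_stage_tsv(cfg: RunConfig, name: str, stage: str) -> pd.DataFrame:
    path = cfg.out_dir / name
    if not path.exists():
        raise PipelineError(
            f"stage 'integrate' needs {path} (run stage {stage!r} first)"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def stage_integrate(cfg: RunConfig) -> dict[str, Path]:
    variants = _variants(cfg, "integrate")
    props = load_default_properties()
    calls = _read_stage_tsv(cfg, "stability_calls.tsv", "stability").set_index("variant")
    chan = _read_stage_tsv(cfg, "channel_scores.tsv", "channel").set_index("variant")
    dyn = _read_stage_tsv(cfg, "dynamics_metrics.tsv", "dynamics")

    names = ["WT"] + [str(v) for v in variants]
    table = pd.DataFrame(index=pd.Index(names, name="variant"))
    by_name = {str(v): v for v in variants}
    table["ddg_if"] = calls["ddg_if"].reindex(names).fillna(0.0)
    table["ddg_of"] = calls["ddg_of"].reindex(names).fillna(0.0)
    table["ddg_max"] = calls["ddg_max"].reindex(names).fillna(0.0)
    table["destabilizing"] = (
        calls["destabilizing"].reindex(names).astype("boolean").fillna(False).astype(bool)
    )
    table["channel_score"] = chan["channel_score"].reindex(names).fillna(0.0)
    table["hydropathy_delta"] = [
        delta_property(by_name[n], props, "hydropathy") if n in by_name else 0.0
        for n in names
    ]
    n_pc = int(cfg.params["n_components"])
    for conf, sub in dyn.groupby("conformation"):
        sub = sub.set_index("variant")
        for j in range(1, n_pc + 1):
            col = f"altered_pc{j}_{conf.lower()}"
            table[col] = (
                sub[f"altered_pc{j}"].reindex(names).astype("boolean")
            )
        table[f"coupling_class_{conf.lower()}"] = sub["coupling_class"].reindex(names)

    thresh_kcal = kbt_threshold_kcal(
        float(cfg.params["threshold_kbt"]), float(cfg.params["temperature"])
    )
    # strict > cutoffs; the ddG call itself uses >= inside stability_calls,
    # so the boolean 'destabilizing' column carries the canonical rule
    thresholds = {
        "ddg_if": thresh_kcal,
        "ddg_of": thresh_kcal,
        "ddg_max": thresh_kcal,
        "channel_score": uncharged_reference(props),
        "hydropathy_delta": float(cfg.params["hydropathy_cutoff"]),
    }
    disc = discretize_metrics(table, thresholds)
    for col in [c for c in disc.columns if c.startswith("coupling_class_")]:
        disc[col] = disc[col].fillna("wt_like")
    dist = variant_distance_matrix(disc)
    coords, stress = nonmetric_mds(
        dist, k=int(cfg.params["mds_k"]), seed=cfg.stage_seed("integrate")
    )
    mds_df = pd.DataFrame(
        coords, index=dist.index, columns=[f"mds{j + 1}" for j in range(coords.shape[1])]
    )
    labels = hierarchical_clusters(dist, int(cfg.params["n_clusters"]))
    clusters_df = pd.DataFrame({"cluster": labels}, index=dist.index)

    outputs = {
        "metrics": _write(table, cfg.out_dir / "metrics.tsv", "integrate", cfg,
                          index=True),
        "discretized": _write(disc, cfg.out_dir / "discretized.tsv", "integrate",
                              cfg, index=True),
        "distances": _write(dist, cfg.out_dir / "distances.tsv", "integrate", cfg,
                            index=True),
        "mds": _write(mds_df, cfg.out_dir / "mds.tsv", "integrate", cfg,
                      extra={"stress": round(stress, 6)}, index=True),
        "clusters": _write(clusters_df, cfg.out_dir / "clusters.tsv", "integrate",
                           cfg, index=True),
    }
    if "predictors" in cfg.paths:
        preds = pd.read_csv(
            cfg.paths["predictors"], sep="\t", comment="#"
        ).set_index("variant")
        merged = merge_predictors(disc, preds)
        outputs["merged"] = _write(
            merged, cfg.out_dir / "metrics_with_predictors.tsv", "integrate", cfg,
            index=True
        )
    return outputs


_STAGE_FN = {
    "cluster": stage_cluster,
    "channel": stage_channel,
    "stability": stage_stability,
    "dynamics": stage_dynamics,
    "integrate": stage_integrate,
}


def run_pipeline(
    config: RunConfig, stages: Sequence[str] | None = None
) -> dict[str, Path]:
    """Execute the requested stages in dependency order; returns the output map."""
    requested = list(stages) if stages else list(STAGES)
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    ordered = [s for s in STAGES if s in requested]
    outputs: dict[str, Path] = {}
    for stage in ordered:
        log.info("running stage %s", stage)
        outputs.update(_STAGE_FN[stage](config))
    manifest = pd.DataFrame(
        [
            {"output": k, "path": str(v.relative_to(config.out_dir))}
            for k, v in sorted(outputs.items())
        ],
        columns=["output", "path"],
    )
    _write(manifest, config.out_dir / "run_manifest.tsv", "run", config)
    return outputs
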
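"""Synthetic helical-bundle structures, trajectories, variants and ΔΔG tables.

This module generates data with the statistical structure the analysis
expects — it stands in for homology models and MD output so every stage is
testable without downloads or simulation:

* ideal α-helical Cα bundles on a ring (consecutive Cα ≈ 3.8 Å);
* trajectories whose gate monitors d1 and θ1 realize a target correlation
  (wild type: strongly negative, decoupled variants: weak or positive) via
  jointly Gaussian amplitudes on two geometric modes, plus optional constant
  mode shifts that displace a variant's PC median out of the benign envelope;
* ΔΔG tables with class-dependent means (pathogenic destabilizing).

All generators are deterministic given their seed; realized monitor
correlations are measured on the generated frames and reported in the
trajectory metadata rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .errors import ParameterError
from .structure import AtomRecord, Conformation, Structure, Trajectory
from .dynamics import MonitorDefinition, compute_monitors
from .stability import DdgRecord
from .variants import CANONICAL_AA, Variant, VariantLabel

__all__ = [
    "BundleSpec",
    "TrajectorySpec",
    "make_bundle_structure",
    "make_trajectory",
    "make_variant_sites",
    "make_ddg_table",
    "default_monitors",
]

_AA3 = {aa: protein_letters_1to3[aa].upper() for aa in CANONICAL_AA}

DEFAULT_CLASS_MEANS = {
    "benign": 0.0,
    "pathogenic": 4.0,
    "vus": 2.0,
    "wt": 0.0,
}


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an ideal Cα helix bundle placed on a ring.

    Defaults mimic a 12-helix transporter fold: 1.5 Å rise and 100°/residue
    twist (ideal α-helix, consecutive Cα ≈ 3.8 Å), helices antiparallel on an
    18 Å ring.  The seed only drives the pseudo-random residue sequence.
    """

    n_helices: int = 12
    residues_per_helix: int = 20
    ring_radius: float = 18.0
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    helix_radius: float = 2.3  # Å, Cα distance from the local helix axis
    antiparallel: bool = True
    chain_id: str = "A"
    start_residue: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ParameterError("n_helices must be >= 1")
        if self.residues_per_helix < 4:
            raise ParameterError("residues_per_helix must be >= 4")
        if min(self.ring_radius, self.rise, self.helix_radius) <= 0:
            raise ParameterError("geometry lengths must be positive")


@dataclass(frozen=True)
class TrajectorySpec:
    """Fluctuation model for synthetic gate dynamics.

    ``amplitude`` (Å) scales the two gate modes; ``monitor_target_corr`` is
    the desired Cor(d1, θ1); ``shift`` adds a constant opening along the
    distance mode (used to displace "altered" variants in PC space);
    ``injected_modes`` overrides the gate modes with explicit
    (displacement field, σ) pairs.
    """

    n_frames: int = 500
    amplitude: float = 2.0
    monitor_target_corr: float = -0.8
    noise_sigma: float = 0.3
    shift: float = 0.0
    seed: int = 0
    injected_modes: tuple[tuple[np.ndarray, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not -1.0 <= self.monitor_target_corr <= 1.0:
            raise ParameterError("|monitor_target_corr| must be <= 1")
        if self.noise_sigma < 0 or self.amplitude < 0:
            raise ParameterError("noise_sigma and amplitude must be >= 0")


def make_bundle_structure(spec: BundleSpec) -> Structure:
    """Ideal α-helical Cα traces on a ring, helix map populated (H1..Hn)."""
    rng = np.random.default_rng(spec.seed)
    aa_codes = rng.choice(list(CANONICAL_AA), size=spec.n_helices * spec.residues_per_helix)
    atoms: list[AtomRecord] = []
    helix_map: dict[str, tuple[int, int]] = {}
    resnum = spec.start_residue
    twist_rad = np.radians(spec.twist)
    for h in range(spec.n_helices):
        phi = 2.0 * np.pi * h / spec.n_helices
        center = np.array(
            [spec.ring_radius * np.cos(phi), spec.ring_radius * np.sin(phi), 0.0]
        )
        direction = 1.0 if (not spec.antiparallel or h % 2 == 0) else -1.0
        start = resnum
        for i in range(spec.residues_per_helix):
            ang = twist_rad * i + phi  # phase offset decorrelates helices
            xyz = center + np.array(
                [
                    spec.helix_radius * np.cos(ang),
                    spec.helix_radius * np.sin(ang),
                    direction * spec.rise * i,
                ]
            )
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    atom_name="CA",
                    residue_name=_AA3[str(aa_codes[resnum - spec.start_residue])],
                    chain_id=spec.chain_id,
                    residue_number=resnum,
                    xyz=tuple(float(c) for c in xyz),
                )
            )
            resnum += 1
        helix_map[f"H{h + 1}"] = (start, resnum - 1)
    return Structure(atoms, Conformation.NA, helix_map)


def default_monitors(structure: Structure, chain_id: str = "A") -> MonitorDefinition:
    """Gate anchors at the ends of the two bundle-threading helices.

    Mirrors the biological convention (intracellular gate pair on one end of
    H4/H10, extracellular pair on the other).  For an n-helix map the
    bundle-threading pair generalizes to helix round(n/3) and its
    half-ring opposite — H4 and H10 for the canonical 12-helix fold.
    """
    n = len(structure.helix_map)
    if n < 2:
        raise ParameterError("default monitors need at least 2 mapped helices")
    i = max(1, round(n / 3))
    j = i + n // 2
    h4, h10 = structure.helix_map[f"H{i}"], structure.helix_map[f"H{j}"]
    return MonitorDefinition(
        a=(chain_id, h4[1]),
        b=(chain_id, h10[1]),
        c=(chain_id, h4[0]),
        d=(chain_id, h10[0]),
    )


def _gate_modes(
    structure: Structure, monitors: MonitorDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Unit displacement fields that move d1 and θ1 nearly independently."""
    coords = structure.coords
    idx = {lab: structure.ca_atom_index(*monitors.anchor(lab)) for lab in "ABCD"}
    A, B, C, D = (coords[idx[lab]] for lab in "ABCD")
    n_atoms = structure.n_atoms

    # distance mode: translate anchor B away from A -> d1 grows linearly
    m_d = np.zeros((n_atoms, 3))
    u = (B - A) / np.linalg.norm(B - A)
    m_d[idx["B"]] = u

    # angle mode: move anchor C perpendicular to arm AC, away from D,
    # so theta1 (vertex A between arms AC and AD) grows ~ linearly
    arm = (C - A) / np.linalg.norm(C - A)
    toward_d = D - A
    perp = toward_d - (toward_d @ arm) * arm
    norm = np.linalg.norm(perp)
    if norm < 1e-9:
        raise ParameterError("collinear anchors: angle mode undefined")
    m_t = np.zeros((n_atoms, 3))
    m_t[idx["C"]] = -perp / norm
    return m_d, m_t


def make_trajectory(
    structure: Structure,
    spec: TrajectorySpec,
    monitors: MonitorDefinition | None = None,
) -> Trajectory:
    """Fluctuating frames around a structure with a target gate correlation.

    With ``monitors`` given (and no explicit ``injected_modes``), frame
    amplitudes on the distance/angle gate modes are drawn jointly Gaussian
    with correlation ``monitor_target_corr``; the realized Pearson and
    Spearman Cor(d1, θ1) are measured on the output and stored in
    ``trajectory.metadata``, with a warning if the target was missed badly.
    """
    rng = np.random.default_rng(spec.seed)
    x0 = structure.coords
    frames = np.broadcast_to(x0, (spec.n_frames, *x0.shape)).copy()

    if spec.injected_modes is not None:
        for mode, sigma in spec.injected_modes:
            mode = np.asarray(mode, dtype=float)
            if mode.shape != x0.shape:
                raise ParameterError("injected mode shape must match the topology")
            amps = rng.normal(0.0, sigma, size=spec.n_frames)
            frames += amps[:, None, None] * mode
    elif monitors is not None and spec.amplitude > 0:
        m_d, m_t = _gate_modes(structure, monitors)
        rho = spec.monitor_target_corr
        cov = spec.amplitude**2 * np.array([[1.0, rho], [rho, 1.0]])
        amps = rng.multivariate_normal([spec.shift, 0.0], cov, size=spec.n_frames)
        frames += amps[:, 0, None, None] * m_d + amps[:, 1, None, None] * m_t
    elif spec.shift != 0.0 and monitors is not None:
        m_d, _ = _gate_modes(structure, monitors)
        frames += spec.shift * m_d

    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)

    traj = Trajectory(structure, frames)
    if monitors is not None:
        mon = compute_monitors(traj, monitors)
        if mon["d1"].nunique() <= 1 or mon["theta1"].nunique() <= 1:
            pearson = spearman = float("nan")  # static frames: undefined
        else:
            pearson = float(np.corrcoef(mon["d1"], mon["theta1"])[0, 1])
            spearman = float(mon["d1"].corr(mon["theta1"], method="spearman"))
        traj.metadata.update(
            realized_corr_pearson=pearson, realized_corr_spearman=spearman
        )
        if (
            spec.injected_modes is None
            and spec.amplitude > 0
            and abs(pearson - spec.monitor_target_corr) > 0.25
        ):
            warnings.warn(
                f"realized Cor(d1,theta1)={pearson:.2f} far from target "
                f"{spec.monitor_target_corr:.2f} (best effort)",
                stacklevel=2,
            )
    return traj


def make_variant_sites(
    structure: Structure,
    n: int,
    mode: str = "uniform",
    seed: int | None = 0,
    radius: float = 15.0,
) -> list[int]:
    """Sample residue positions uniformly or spatially clustered.

    Clustered mode samples within ``radius`` Å of a random seed residue's Cα,
    falling back to the nearest-n residues when the ball is underpopulated.
    """
    modeled = sorted({r for (_, r) in structure.ca_residues()})
    if n > len(modeled):
        raise ParameterError(f"n={n} exceeds {len(modeled)} modeled residues")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        picks = rng.choice(modeled, size=n, replace=False)
        return sorted(int(p) for p in picks)
    if mode != "clustered":
        raise ParameterError(f"unknown mode {mode!r}")
    chain_of: dict[int, str] = {}
    for (c, r) in structure.ca_residues():
        chain_of.setdefault(r, c)
    coords = np.array(
        [structure.atoms[structure.ca_atom_index(chain_of[r], r)].xyz for r in modeled]
    )
    center = int(rng.integers(len(modeled)))
    dist = np.linalg.norm(coords - coords[center], axis=1)
    candidates = np.flatnonzero(dist <= radius)
    if len(candidates) < n:
        candidates = np.argsort(dist)[:n]
    picks = rng.choice(candidates, size=n, replace=False)
    return sorted(int(modeled[i]) for i in picks)


def make_ddg_table(
    variants: Sequence[Variant],
    class_means: dict[str, float] | None = None,
    sigma: float = 1.0,
    seed: int | None = 0,
) -> list[DdgRecord]:
    """ΔΔG ~ Normal(class mean, σ), drawn independently per conformation.

    Default class means (kcal/mol): benign 0, pathogenic 4, VUS 2 — the
    pathogenic/benign separation the analysis is designed to detect.
    """
    means = dict(DEFAULT_CLASS_MEANS if class_means is None else class_means)
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[DdgRecord] = []
    for v in variants:
        if v.label.value not in means:
            raise ParameterError(f"no class mean for label {v.label.value!r}")
        mu = means[v.label.value]
        for conf in (Conformation.IF, Conformation.OF):
            records.append(
                DdgRecord(str(v), conf, float(rng.normal(mu, sigma)))
            )
    return records
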
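"""Structures, trajectories, Cα selections, rigid-body superposition and RMSD.

Structures are Cα-friendly wrappers around PDB ATOM records (author residue
numbering, Å units).  Trajectories are ordered coordinate frames over a fixed
topology; the text interchange format is multi-model PDB, with DCD supported
optionally through MDAnalysis behind the same contract.  Superposition is the
classic least-squares Kabsch fit over an explicit residue-equivalence
selection — equivalences are supplied, never inferred by fragment alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import DegenerateFitError, FormatError, ParameterError, SelectionError

log = logging.getLogger(__name__)

__all__ = [
    "Conformation",
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "superpose_trajectory",
    "ca_rmsd",
    "kabsch",
]


class Conformation(str, Enum):
    """Transport-cycle endpoint a model represents (rocker-switch convention)."""

    IF = "IF"  # inward-facing
    OF = "OF"  # outward-facing
    NA = "NA"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise FormatError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )
        if not all(np.isfinite(self.xyz)):
            raise FormatError(f"non-finite coordinate for atom {self.serial}")


@dataclass
class Structure:
    """An ordered list of atom records plus conformation and helix annotation.

    ``helix_map`` maps helix ids (``"H1"`` .. ``"H12"``) to inclusive author
    residue-number ranges; ranges must not overlap and every mapped residue
    must be present among the atoms.
    """

    atoms: list[AtomRecord]
    conformation: Conformation = Conformation.NA
    helix_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.atom_name == "CA":
                key = (a.chain_id, a.residue_number)
                if key in seen:
                    raise FormatError(
                        f"duplicate CA for chain {key[0]} residue {key[1]}"
                    )
                seen.add(key)
        self._ca_index = {
            (a.chain_id, a.residue_number): i
            for i, a in enumerate(self.atoms)
            if a.atom_name == "CA"
        }
        self._validate_helix_map()

    def _validate_helix_map(self) -> None:
        ranges = sorted(self.helix_map.items(), key=lambda kv: kv[1][0])
        present = {num for (_, num) in self._ca_index}
        prev_end = None
        for name, (lo, hi) in ranges:
            if lo > hi:
                raise FormatError(f"helix {name}: inverted range {lo}-{hi}")
            if prev_end is not None and lo <= prev_end:
                raise FormatError(f"helix {name}: overlaps previous helix range")
            prev_end = hi
            missing = [r for r in range(lo, hi + 1) if r not in present]
            if missing:
                raise FormatError(
                    f"helix {name}: residues {missing[:5]} not present in structure"
                )

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def ca_atom_index(self, chain_id: str, residue_number: int) -> int:
        try:
            return self._ca_index[(chain_id, residue_number)]
        except KeyError:
            raise SelectionError(
                f"no CA atom for chain {chain_id!r} residue {residue_number}"
            ) from None

    def ca_residues(self) -> list[tuple[str, int]]:
        """All (chain, residue_number) pairs that have a Cα, in atom order."""
        return sorted(self._ca_index, key=self._ca_index.get)

    def residue_name_at(self, chain_id: str, residue_number: int) -> str:
        return self.atoms[self.ca_atom_index(chain_id, residue_number)].residue_name

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ParameterError(
                f"coords shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        atoms = [
            AtomRecord(a.serial, a.atom_name, a.residue_name, a.chain_id,
                       a.residue_number, tuple(float(c) for c in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.conformation, dict(self.helix_map))


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology (Å)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None  # metadata only (e.g. ps/frame)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ParameterError(f"frames must be (n, atoms, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise FormatError("trajectory must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class Selection:
    """Ordered, unique (chain_id, residue_number) pairs resolved as Cα atoms."""

    pairs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ParameterError("selection pairs must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_residues(cls, residues: Iterable[int], chain_id: str = "A") -> "Selection":
        return cls(tuple((chain_id, int(r)) for r in residues))

    @classmethod
    def from_helices(
        cls, structure: Structure, helix_ids: Sequence[str] | None = None
    ) -> "Selection":
        """All Cα in the given helices (default: every mapped helix) in residue order."""
        ids = list(helix_ids) if helix_ids is not None else sorted(
            structure.helix_map, key=lambda h: structure.helix_map[h][0]
        )
        pairs: list[tuple[str, int]] = []
        chain_of: dict[int, str] = {}
        for (c, r) in structure.ca_residues():
            chain_of.setdefault(r, c)
        for hid in ids:
            if hid not in structure.helix_map:
                raise SelectionError(f"unknown helix id {hid!r}")
            lo, hi = structure.helix_map[hid]
            pairs.extend((chain_of[r], r) for r in range(lo, hi + 1) if r in chain_of)
        return cls(tuple(pairs))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "Selection":
        """Read a two-column (chain, residue_number) TSV, '#' comments allowed."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"selection line needs 2 columns: {line!r}")
            pairs.append((parts[0], int(parts[1])))
        return cls(tuple(pairs))

    def atom_indices(self, structure: Structure) -> np.ndarray:
        return np.array(
            [structure.ca_atom_index(c, r) for (c, r) in self.pairs], dtype=int
        )


# ---------------------------------------------------------------------------
# PDB I/O


def _model_atoms(model, path: Path, model_index: int) -> list[AtomRecord]:
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.get_id()
            if het.strip():  # HETATM (waters, ligands) ignored by default
                continue
            if icode.strip():
                raise FormatError(
                    f"{path}: insertion code {icode!r} at residue {resseq} "
                    "not supported"
                )
            for atom in residue:
                altloc = atom.get_altloc()
                if altloc not in (" ", "A"):
                    continue
                records.append(
                    AtomRecord(
                        serial=int(atom.serial_number or len(records) + 1),
                        atom_name=atom.get_name(),
                        residue_name=residue.get_resname(),
                        chain_id=chain.id,
                        residue_number=int(resseq),
                        xyz=tuple(float(c) for c in atom.coord),
                    )
                )
    return records


def read_structure(
    path: Union[str, Path],
    conformation: Conformation = Conformation.NA,
    helix_map: dict[str, tuple[int, int]] | None = None,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only ATOM records are kept (HETATM ignored); altLoc blank or 'A' only;
    insertion codes are rejected.  If the file holds several MODEL blocks the
    first is used and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdb = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc
    models = list(pdb)
    if not models:
        raise FormatError(f"{path}: no models / atoms found")
    if len(models) > 1:
        log.warning("%s: %d MODEL blocks; using the first", path, len(models))
    atoms = _model_atoms(models[0], path, 0)
    if not atoms:
        raise FormatError(f"{path}: zero ATOM records")
    return Structure(atoms, Conformation(conformation), helix_map or {})


def _atom_line(a: AtomRecord, serial: int, xyz: Sequence[float]) -> str:
    name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
    element = a.atom_name.strip()[:1]
    return (
        f"ATOM  {serial:5d} {name} {a.residue_name:>3s} {a.chain_id:1s}"
        f"{a.residue_number:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def write_structure(structure: Structure, path: Union[str, Path]) -> None:
    """Write ATOM records (fixed-column PDB dialect, 3-decimal Å)."""
    lines = [
        _atom_line(a, i + 1, a.xyz) for i, a in enumerate(structure.atoms)
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: Union[str, Path], topology: Structure) -> Trajectory:
    """Read a multi-model PDB (or ``.dcd`` via MDAnalysis) as a trajectory.

    Every model must carry exactly the topology's atoms in the same order;
    a mismatch raises :class:`FormatError` naming the model index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".dcd":
        return _read_dcd(path, topology)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdb = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"{path}: {exc}") from exc
    models = list(pdb)
    if not models:
        raise FormatError(f"{path}: no models found")
    expected = [(a.chain_id, a.residue_number, a.atom_name) for a in topology.atoms]
    frames = np.empty((len(models), topology.n_atoms, 3), dtype=float)
    for i, model in enumerate(models):
        atoms = _model_atoms(model, path, i)
        if len(atoms) != len(expected):
            raise FormatError(
                f"{path}: model {i + 1} has {len(atoms)} atoms, "
                f"topology has {len(expected)}"
            )
        got = [(a.chain_id, a.residue_number, a.atom_name) for a in atoms]
        if got != expected:
            raise FormatError(f"{path}: model {i + 1} atom order differs from topology")
        frames[i] = [a.xyz for a in atoms]
    return Trajectory(topology, frames)


def _read_dcd(path: Path, topology: Structure) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DCD support requires MDAnalysis (install the 'dcd' extra)"
        ) from exc
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    u.load_new(str(path))
    if len(u.atoms) != topology.n_atoms:
        raise FormatError(
            f"{path}: DCD atom count {len(u.atoms)} != topology {topology.n_atoms}"
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if frames.shape[0] == 0:
        raise FormatError(f"{path}: DCD holds zero frames")
    return Trajectory(topology, frames)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    lines: list[str] = []
    for i, frame in enumerate(traj.frames):
        lines.append(f"MODEL     {i + 1:4d}")
        for j, a in enumerate(traj.topology.atoms):
            lines.append(_atom_line(a, j + 1, frame[j]))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Superposition and RMSD


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (both (n, 3)).

    Returns (R, t) with the proper rotation R (det = +1) such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ParameterError("kabsch expects matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise DegenerateFitError("rigid fit needs at least 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - mc @ R.T
    return R, t


def superpose_trajectory(
    traj: Trajectory, reference: Structure, selection: Selection
) -> Trajectory:
    """Rigidly fit every frame onto ``reference`` over the selection Cα.

    Non-selected atoms are carried along by the same rigid transform, so
    intra-frame geometry is preserved exactly.
    """
    if len(selection) < 3:
        raise DegenerateFitError("superposition selection needs >= 3 residues")
    ref_xyz = reference.coords[selection.atom_indices(reference)]
    idx = selection.atom_indices(traj.topology)
    out = np.empty_like(traj.frames)
    for i, frame in enumerate(traj.frames):
        R, t = kabsch(frame[idx], ref_xyz)
        out[i] = frame @ R.T + t
    return Trajectory(traj.topology, out, traj.frame_interval, dict(traj.metadata))


FrameLike = Union[Structure, tuple[Structure, np.ndarray]]


def _selection_coords(obj: FrameLike, selection: Selection) -> np.ndarray:
    if isinstance(obj, Structure):
        return obj.coords[selection.atom_indices(obj)]
    topology, coords = obj
    coords = np.asarray(coords, dtype=float)
    return coords[selection.atom_indices(topology)]


def ca_rmsd(a: FrameLike, b: FrameLike, selection: Selection) -> float:
    """Cα RMSD (Å) over the selection after optimal rigid superposition.

    Arguments may be structures or ``(topology, frame_coords)`` pairs; the
    result is symmetric and invariant to rigid transforms of either input.
    """
    P = _selection_coords(a, selection)
    Q = _selection_coords(b, selection)
    R, t = kabsch(P, Q)
    diff = P @ R.T + t - Q
    return float(np.sqrt((diff**2).sum(axis=1).mean()))
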
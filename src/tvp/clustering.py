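"""Spatial clustering of variant sites with a permutation null.

Variant residues are joined into a contact graph (Cα–Cα distance at or below a
threshold, default 15 Å).  Connected components are the spatial clusters;
compactness is the geometric mean of component sizes (small = compact),
density the number of within-cluster edges (large = clustered), and
normalized density their ratio.  Significance comes from permuting site
placement uniformly over all residues with modeled Cα.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError, SelectionError
from .structure import Structure

__all__ = [
    "build_contact_graph",
    "cluster_stats",
    "permutation_test",
    "ClusterStats",
    "PermutationResult",
]

Statistic = Literal["compactness", "density", "normalized_density"]

DEFAULT_CONTACT_THRESHOLD = 15.0  # Å, Cα–Cα


@dataclass(frozen=True)
class ClusterStats:
    components: tuple[frozenset[int], ...]
    compactness: float  # geometric mean of component sizes
    density: int  # edges within components (= all edges of a threshold graph)
    normalized_density: float

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted((len(c) for c in self.components), reverse=True))


@dataclass(frozen=True)
class PermutationResult:
    statistic: Statistic
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    exhaustive: bool


def _site_coords(structure: Structure, positions: Sequence[int]) -> np.ndarray:
    chain_of = {}
    for (c, r) in structure.ca_residues():
        chain_of.setdefault(r, c)
    coords = []
    for p in positions:
        if p not in chain_of:
            raise SelectionError(f"no modeled CA for residue {p}")
        idx = structure.ca_atom_index(chain_of[p], p)
        coords.append(structure.atoms[idx].xyz)
    return np.asarray(coords, dtype=float)


def build_contact_graph(
    structure: Structure,
    positions: Sequence[int],
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> nx.Graph:
    """Graph over variant sites; edges join Cα pairs within ``threshold`` Å."""
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    positions = list(dict.fromkeys(int(p) for p in positions))
    xyz = _site_coords(structure, positions)
    g = nx.Graph(threshold=threshold)
    for p, coord in zip(positions, xyz):
        g.add_node(p, xyz=tuple(coord))
    for (i, p), (j, q) in itertools.combinations(enumerate(positions), 2):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d <= threshold:
            g.add_edge(p, q, distance=d)
    return g


def _stats_from_adjacency(adj: np.ndarray) -> tuple[float, int, float]:
    """(compactness, density, normalized_density) from a boolean adjacency."""
    n = adj.shape[0]
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp).astype(float)
    compactness = float(np.exp(np.mean(np.log(sizes))))
    density = int(np.triu(adj, k=1).sum())
    return compactness, density, density / compactness


def cluster_stats(graph: nx.Graph) -> ClusterStats:
    """Component partition plus compactness / density / normalized density."""
    if graph.number_of_nodes() == 0:
        raise ParameterError("empty contact graph")
    comps = tuple(frozenset(c) for c in nx.connected_components(graph))
    sizes = np.array([len(c) for c in comps], dtype=float)
    compactness = float(np.exp(np.mean(np.log(sizes))))
    density = graph.number_of_edges()
    return ClusterStats(comps, compactness, density, density / compactness)


def _observed_value(stats: tuple[float, int, float], statistic: Statistic) -> float:
    return {
        "compactness": stats[0],
        "density": float(stats[1]),
        "normalized_density": stats[2],
    }[statistic]


def permutation_test(
    structure: Structure,
    observed_positions: Sequence[int],
    statistic: Statistic = "normalized_density",
    n_perm: int = 9999,
    seed: int | None = None,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    exhaustive: bool = False,
    universe: Sequence[int] | None = None,
) -> PermutationResult:
    """Permutation significance of spatial clustering among variant sites.

    Each permutation redraws ``len(observed_positions)`` sites uniformly
    without replacement from the universe of residues with modeled Cα.  The
    add-one estimator ``p = (1 + extreme)/(1 + n_perm)`` is used; compactness
    counts null values <= observed (more compact is smaller), the density
    statistics count null values >= observed.  ``exhaustive=True`` enumerates
    every site combination instead of sampling (small problems only).
    """
    observed_positions = list(dict.fromkeys(int(p) for p in observed_positions))
    k = len(observed_positions)
    if k < 2:
        raise ParameterError("need at least 2 observed positions")
    if universe is None:
        universe = sorted({r for (_, r) in structure.ca_residues()})
    universe = list(universe)
    if k > len(universe):
        raise ParameterError(
            f"{k} observed positions exceed {len(universe)} modeled residues"
        )
    if not exhaustive and n_perm < 1:
        raise ParameterError("n_perm must be >= 1")

    coords = _site_coords(structure, universe)
    dist = squareform(pdist(coords))
    adj_full = dist <= threshold
    np.fill_diagonal(adj_full, False)
    index_of = {p: i for i, p in enumerate(universe)}
    try:
        obs_idx = np.array([index_of[p] for p in observed_positions])
    except KeyError as exc:
        raise SelectionError(f"observed position {exc.args[0]} not in universe") from None

    observed = _observed_value(
        _stats_from_adjacency(adj_full[np.ix_(obs_idx, obs_idx)]), statistic
    )

    if exhaustive:
        draws = itertools.combinations(range(len(universe)), k)
        null = np.array(
            [
                _observed_value(
                    _stats_from_adjacency(adj_full[np.ix_(idx, idx)]), statistic
                )
                for idx in (np.array(c) for c in draws)
            ]
        )
        n_draws = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(len(universe), size=k, replace=False)
            null[i] = _observed_value(
                _stats_from_adjacency(adj_full[np.ix_(idx, idx)]), statistic
            )
        n_draws = n_perm

    if statistic == "compactness":
        extreme = int((null <= observed).sum())
    else:
        extreme = int((null >= observed).sum())
    p = (1 + extreme) / (1 + n_draws)
    return PermutationResult(statistic, observed, null, p, n_draws, exhaustive)
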
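"""Trajectory analysis: gate monitors, Cartesian Cα PCA, benign envelopes,
subsampled t-statistics, Spearman/BH correlation matrices and coupling classes.

The conformational monitors are two gate distances and six angles among four
Cα anchors at the ends of the gate helices (defaults: S124/S436 for the
intracellular opening d1, L101/L413 for the extracellular opening d2).  In the
wild type d1 and the first angle θ1 are strongly negatively correlated — the
two gates move reciprocally during the inward/outward transition — and a
variant's Spearman Cor(d1, θ1) classifies its coupling as wild-type-like
(ρ ≤ −0.5), diminished (−0.5 < ρ ≤ 0) or sign-altered (ρ > 0).

PCA runs on flattened Cartesian Cα coordinates of pre-superposed frames.
"Altered" calls compare a variant's median principal-component score against
an envelope fitted to reference (wild-type plus benign) simulations: the
shortest interval holding the densest 75% of reference scores in one
dimension, or a total-least-squares line with the narrowest residual band
holding 60% in a PC plane.  Envelopes are closed sets — a median exactly on
the boundary is not altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateFitError, ParameterError
from .structure import Selection, Structure, Trajectory

__all__ = [
    "MonitorDefinition",
    "compute_monitors",
    "CartesianPCA",
    "fit_pca",
    "project_frames",
    "HighestDensityInterval",
    "density_interval",
    "PrincipalAxisBand",
    "line_band",
    "flag_altered",
    "subsampled_t",
    "correlation_matrix",
    "CorrelationResult",
    "CouplingClass",
    "classify_coupling",
    "selection_matrix",
]

Anchor = tuple[str, int]

#: Default six vertex angles among the four gate anchors A=S124, B=S436,
#: C=L101, D=L413.  The first triple defines θ1 (vertex A subtending C and D),
#: whose correlation with d1 is the coupling diagnostic.  The enumeration is
#: a shipped convention, fully overridable in :class:`MonitorDefinition`.
DEFAULT_ANGLE_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("A", "C", "D"),
    ("B", "C", "D"),
    ("C", "A", "B"),
    ("D", "A", "B"),
    ("A", "B", "D"),
    ("B", "A", "C"),
)


@dataclass(frozen=True)
class MonitorDefinition:
    """Four Cα anchors plus six (vertex, arm, arm) angle triples.

    d1 is the A–B distance, d2 the C–D distance; triples are spelled with the
    anchor labels "A".."D" so any angle convention is expressible.
    """

    a: Anchor = ("A", 124)
    b: Anchor = ("A", 436)
    c: Anchor = ("A", 101)
    d: Anchor = ("A", 413)
    angle_triples: tuple[tuple[str, str, str], ...] = DEFAULT_ANGLE_TRIPLES

    def __post_init__(self) -> None:
        anchors = (self.a, self.b, self.c, self.d)
        if len(set(anchors)) != 4:
            raise ParameterError("the four anchors must be distinct residues")
        if len(self.angle_triples) != 6:
            raise ParameterError("exactly six angle triples required")
        for t in self.angle_triples:
            if len(set(t)) != 3 or not set(t) <= {"A", "B", "C", "D"}:
                raise ParameterError(f"bad angle triple {t!r}")

    def anchor(self, label: str) -> Anchor:
        return {"A": self.a, "B": self.b, "C": self.c, "D": self.d}[label]


def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise DegenerateFitError("coincident anchor coordinates (zero-length arm)")
    cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def compute_monitors(traj: Trajectory, defn: MonitorDefinition) -> pd.DataFrame:
    """Per-frame gate monitors: columns d1, d2 (Å) and theta1..theta6 (degrees)."""
    top = traj.topology
    idx = {lab: top.ca_atom_index(*defn.anchor(lab)) for lab in "ABCD"}
    pos = {lab: traj.frames[:, i, :] for lab, i in idx.items()}
    out = pd.DataFrame(index=pd.RangeIndex(traj.n_frames, name="frame"))
    d1 = np.linalg.norm(pos["A"] - pos["B"], axis=1)
    d2 = np.linalg.norm(pos["C"] - pos["D"], axis=1)
    if np.any(d1 == 0) or np.any(d2 == 0):
        raise DegenerateFitError("coincident anchor coordinates")
    out["d1"] = d1
    out["d2"] = d2
    for k, (vertex, arm1, arm2) in enumerate(defn.angle_triples, start=1):
        out[f"theta{k}"] = _angles_deg(
            pos[arm1] - pos[vertex], pos[arm2] - pos[vertex]
        )
    return out


# ---------------------------------------------------------------------------
# Cartesian PCA


def selection_matrix(traj: Trajectory, selection: Selection | None = None) -> np.ndarray:
    """Flatten selection Cα coordinates to an (n_frames, 3·n_sel) sample matrix."""
    if selection is None:
        idx = np.arange(traj.topology.n_atoms)
    else:
        idx = selection.atom_indices(traj.topology)
    return traj.frames[:, idx, :].reshape(traj.n_frames, -1)


class CartesianPCA(BaseEstimator):
    """PCA of flattened Cartesian coordinates (sklearn estimator).

    Fitted attributes: ``mean_``, ``components_`` (orthonormal rows, descending
    eigenvalue), ``explained_variance_`` (eigenvalues, ddof=1).  The sign of
    each component is fixed by making its largest-magnitude loading positive,
    so fits are deterministic.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "CartesianPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("PCA needs a 2D sample matrix with >= 2 frames")
        self._pca = PCA(n_components=self.n_components, svd_solver="full").fit(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.explained_variance_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_pca(
    frames: Union[np.ndarray, Trajectory],
    selection: Selection | None = None,
    n_components: int | None = None,
) -> CartesianPCA:
    """Fit :class:`CartesianPCA` on a sample matrix or a trajectory selection."""
    if isinstance(frames, Trajectory):
        frames = selection_matrix(frames, selection)
    return CartesianPCA(n_components=n_components).fit(frames)


def project_frames(
    frames: Union[np.ndarray, Trajectory],
    model: CartesianPCA,
    k: int | None = None,
    selection: Selection | None = None,
) -> np.ndarray:
    """Centered scores of frames on the first ``k`` components."""
    if isinstance(frames, Trajectory):
        frames = selection_matrix(frames, selection)
    scores = model.transform(frames)
    if k is not None:
        if k > scores.shape[1]:
            raise ParameterError(
                f"k={k} exceeds the {scores.shape[1]} stored components"
            )
        scores = scores[:, :k]
    return scores


# ---------------------------------------------------------------------------
# Density envelopes


def _shortest_interval(x: np.ndarray, mass: float) -> tuple[float, float]:
    """Shortest closed interval over order statistics covering ceil(mass·n)
    points; ties broken toward the lower interval."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    m = int(np.ceil(mass * n))
    m = max(m, 1)
    widths = xs[m - 1 :] - xs[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (= lowest) minimizer
    return float(xs[i]), float(xs[i + m - 1])


class HighestDensityInterval(BaseEstimator):
    """Shortest interval containing the densest ``mass`` fraction of samples.

    Fitted attributes ``low_`` / ``high_``; the interval is closed, so values
    on the boundary count as contained.
    """

    def __init__(self, mass: float = 0.75):
        self.mass = mass

    def fit(self, x: np.ndarray, y=None) -> "HighestDensityInterval":
        x = np.asarray(x, dtype=float).ravel()
        if not 0 < self.mass <= 1:
            raise ParameterError(f"mass must lie in (0, 1], got {self.mass}")
        if x.size < 10:
            raise ParameterError("need at least 10 reference samples")
        self.low_, self.high_ = _shortest_interval(x, self.mass)
        return self

    def contains(self, value: float) -> bool:
        return bool(self.low_ <= value <= self.high_)


def density_interval(reference_scores: np.ndarray, mass: float = 0.75) -> HighestDensityInterval:
    return HighestDensityInterval(mass=mass).fit(reference_scores)


class PrincipalAxisBand(BaseEstimator):
    """Total-least-squares line in a PC plane with the narrowest residual band
    holding the densest ``mass`` fraction of reference samples.

    Fitted attributes: ``point_`` (centroid), ``direction_`` (unit vector of
    the first principal axis), residual band ``res_low_``/``res_high_`` and
    ``halfwidth_`` (half of the band width).  Residuals are signed orthogonal
    distances from the line; the band is a closed set.
    """

    def __init__(self, mass: float = 0.60):
        self.mass = mass

    def fit(self, X: np.ndarray, y=None) -> "PrincipalAxisBand":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ParameterError("band fitting expects (n, 2) samples")
        if X.shape[0] < 10:
            raise ParameterError("need at least 10 reference samples")
        self.point_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        if not np.any(cov > 1e-30):
            raise DegenerateFitError("zero-variance cloud; no principal axis")
        w, V = np.linalg.eigh(cov)
        direction = V[:, int(np.argmax(w))]
        if direction[int(np.argmax(np.abs(direction)))] < 0:
            direction = -direction
        self.direction_ = direction
        res = self.residual(X)
        self.res_low_, self.res_high_ = _shortest_interval(res, self.mass)
        self.halfwidth_ = (self.res_high_ - self.res_low_) / 2.0
        return self

    def residual(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        normal = np.array([-self.direction_[1], self.direction_[0]])
        return (X - self.point_) @ normal

    def contains(self, residual_value: float) -> bool:
        return bool(self.res_low_ <= residual_value <= self.res_high_)


def line_band(reference_scores_2d: np.ndarray, mass: float = 0.60) -> PrincipalAxisBand:
    return PrincipalAxisBand(mass=mass).fit(reference_scores_2d)


Envelope = Union[HighestDensityInterval, PrincipalAxisBand]


def flag_altered(variant_scores: np.ndarray, envelope: Envelope) -> bool:
    """True iff the variant's median score falls strictly outside the envelope.

    For a 1D interval the median of the scores is tested; for a 2D band the
    median signed residual from the line.  Envelopes are closed, so a median
    exactly on the boundary is not altered.
    """
    scores = np.asarray(variant_scores, dtype=float)
    if scores.size == 0:
        raise ParameterError("need at least one score")
    if isinstance(envelope, PrincipalAxisBand):
        med = float(np.median(envelope.residual(scores)))
    else:
        med = float(np.median(scores.ravel()))
    return not envelope.contains(med)


# ---------------------------------------------------------------------------
# Time-series statistics


def subsampled_t(
    series_a: Sequence[float],
    series_b: Sequence[float],
    n_sub: int = 100,
    rounds: int = 10,
    seed: int | None = None,
) -> float:
    """Median Welch t over rounds of paired subsamples of autocorrelated series.

    Each round draws ``n_sub`` observations without replacement from each
    series (no silent replacement sampling) and computes Welch's t; the median
    over rounds damps the effective-sample-size inflation of correlated MD
    time series.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) < n_sub or len(b) < n_sub:
        raise ParameterError(
            f"both series must have >= n_sub={n_sub} points (got {len(a)}, {len(b)})"
        )
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    ts = []
    for _ in range(rounds):
        sa = rng.choice(a, size=n_sub, replace=False)
        sb = rng.choice(b, size=n_sub, replace=False)
        t, _ = stats.ttest_ind(sa, sb, equal_var=False)
        ts.append(float(t))
    return float(np.median(ts))


@dataclass(frozen=True)
class CorrelationResult:
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame  # Benjamini–Hochberg over the upper triangle


def correlation_matrix(series: pd.DataFrame) -> CorrelationResult:
    """Pairwise Spearman ρ with BH-adjusted p-values (one family).

    Constant columns yield undefined correlations, reported as NaN with a
    warning; the BH family is the upper triangle of defined pairs.
    """
    if series.shape[0] < 3:
        raise ParameterError("need at least 3 frames")
    if series.shape[1] < 2:
        raise ParameterError("need at least 2 series")
    cols = list(series.columns)
    m = len(cols)
    rho = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p_raw = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    np.fill_diagonal(p_raw.values, 0.0)
    pairs, pvals = [], []
    for i in range(m):
        for j in range(i + 1, m):
            x, y = series.iloc[:, i], series.iloc[:, j]
            if x.nunique() <= 1 or y.nunique() <= 1:
                warnings.warn(
                    f"constant series {cols[i] if x.nunique() <= 1 else cols[j]!r}: "
                    "Spearman rho undefined",
                    stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
            if np.isfinite(p):
                pairs.append((i, j))
                pvals.append(p)
    p_adj = p_raw.copy()
    if pvals:
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for (i, j), q in zip(pairs, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = q
    return CorrelationResult(rho, p_raw, p_adj)


class CouplingClass(str, Enum):
    WT_LIKE = "wt_like"
    DIMINISHED = "diminished"
    SIGN_ALTERED = "sign_altered"


def classify_coupling(rho: float) -> CouplingClass:
    """Gate-coupling class from Cor(d1, θ1).

    ρ ≤ −0.5: wild-type-like reciprocal gating; −0.5 < ρ ≤ 0: diminished
    coupling; ρ > 0: sign-altered (decoupled) transition.
    """
    if not np.isfinite(rho) or not -1.0 <= rho <= 1.0:
        raise ParameterError(f"rho must lie in [-1, 1], got {rho}")
    if rho <= -0.5:
        return CouplingClass.WT_LIKE
    if rho <= 0.0:
        return CouplingClass.DIMINISHED
    return CouplingClass.SIGN_ALTERED
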
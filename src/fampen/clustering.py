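"""Trait-by-relative correlation matrix and its hierarchical clustering.

For each of the 12 traits, three per-family columns are formed — the
proband value, the sibling value (within-family mean if several siblings)
and the parent score (mother/father average) — giving 36 columns. Each
column is z-scored and polarity-oriented (cognitive measures negated so
higher always indexes impairment), and all pairwise Pearson correlations
are computed across families with pairwise-complete deletion. The 36x36
matrix is then clustered: each row of the correlation matrix is treated as
a feature vector, with Ward linkage on Euclidean distances, and the number
of clusters is chosen at the elbow of the within-cluster sum-of-squares
(WSS) curve, operationalised as the largest second difference of WSS with
ties broken toward smaller k.

The role-pair quadrant summary turns the qualitative reading of the matrix
("parent traits track sibling traits more closely than proband traits")
into one mean correlation per role pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import FamilyTable, standardize_and_orient
from .exceptions import DegenerateDataError
from .traits import TraitSpec

CLUSTER_ROLES = ("proband", "sibling", "parent")

#: Fraction of the total WSS drop the strongest elbow must explain before a
#: k selection is considered confident.
_ELBOW_CONFIDENCE = 0.1


@dataclass
class TraitRelativeMatrix:
    """Pairwise correlations between all (trait, role) column pairs."""

    labels: list[tuple[str, str]]         # (trait, role)
    values: np.ndarray                    # square, symmetric, unit diagonal
    n_obs: np.ndarray                     # pairwise-complete family counts
    dropped: list[tuple[tuple[str, str], str]] = field(default_factory=list)
    low_n_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.labels)

    def label_strings(self) -> list[str]:
        return [f"{role}:{trait}" for trait, role in self.labels]

    def to_frame(self) -> pd.DataFrame:
        idx = self.label_strings()
        return pd.DataFrame(self.values, index=idx, columns=idx)


@dataclass
class ClusterSolution:
    """One flat cut of the merge tree, with the WSS curve that chose it."""

    k: int
    assignments: dict[tuple[str, str], int]
    merge_tree: np.ndarray                # scipy linkage matrix
    wss_curve: dict[int, float]
    low_confidence: bool = False


@dataclass
class ElbowResult:
    k: int
    low_confidence: bool


def build_trait_relative_matrix(
    table: FamilyTable, min_overlap: int = 3
) -> TraitRelativeMatrix:
    """Assemble the z-scored, polarity-oriented trait-by-role correlation matrix.

    Columns with fewer than two observations or zero variance are dropped
    with a warning and recorded in ``dropped``. Correlations whose
    pairwise-complete family count falls below ``min_overlap`` are recorded
    in ``low_n_pairs`` and set to 0.
    """
    columns: dict[tuple[str, str], pd.Series] = {}
    dropped: list[tuple[tuple[str, str], str]] = []
    getters = {
        "proband": table.proband_scores,
        "sibling": table.sibling_scores,
        "parent": table.parent_scores,
    }
    for trait in table.trait_names:
        spec = table.spec(trait)
        for role in CLUSTER_ROLES:
            raw = getters[role](trait)
            try:
                z = standardize_and_orient(raw.to_numpy(), spec)
            except DegenerateDataError as exc:
                dropped.append(((trait, role), str(exc)))
                warnings.warn(f"dropping column {role}:{trait}: {exc}", stacklevel=2)
                continue
            columns[(trait, role)] = pd.Series(z.to_numpy(), index=raw.index)

    if len(columns) < 2:
        raise DegenerateDataError("fewer than two usable columns for the matrix")
    frame = pd.DataFrame(columns)
    labels = list(frame.columns)
    obs = frame.notna().to_numpy(dtype=int)
    n_obs = obs.T @ obs
    corr = frame.corr(method="pearson", min_periods=2).to_numpy()

    low_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = []
    m = len(labels)
    for i in range(m):
        for j in range(i + 1, m):
            if n_obs[i, j] < min_overlap or not np.isfinite(corr[i, j]):
                low_pairs.append((labels[i], labels[j]))
                corr[i, j] = corr[j, i] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    if low_pairs:
        warnings.warn(
            f"{len(low_pairs)} correlation(s) had < {min_overlap} overlapping "
            "families and were set to 0", stacklevel=2)
    return TraitRelativeMatrix(
        labels=labels, values=corr, n_obs=n_obs,
        dropped=dropped, low_n_pairs=low_pairs,
    )


def _wss(rows: np.ndarray, assignment: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(assignment):
        block = rows[assignment == c]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


class TraitRelativeClustering(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering of correlation-matrix rows.

    Parameters
    ----------
    n_clusters : int, optional
        Fixed number of clusters; when None, chosen by the elbow rule.
    k_max : int
        Largest k considered when selecting the elbow.
    linkage : str
        scipy linkage method (default ``"ward"``, the WSS-consistent choice).

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : cluster id per row (0-based).
    k_ : number of clusters used.
    linkage_ : scipy linkage matrix (the merge tree).
    wss_curve_ : dict k -> within-cluster sum of squares.
    low_confidence_ : True when the WSS curve showed no clear elbow (flat
        or weakly curved); k then defaults to 2 if it was not fixed.
    """

    def __init__(self, n_clusters: int | None = None, k_max: int = 10,
                 linkage: str = "ward"):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.linkage = linkage

    def fit(self, X, y=None):
        rows = np.asarray(X, dtype=float)
        if rows.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n = rows.shape[0]
        if self.n_clusters is not None and not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        self.linkage_ = hierarchy.linkage(rows, method=self.linkage)

        upper = min(self.k_max + 1, n)
        cuts = {
            k: hierarchy.fcluster(self.linkage_, k, criterion="maxclust") - 1
            for k in range(1, upper + 1)
        }
        self.wss_curve_ = {k: _wss(rows, cut) for k, cut in cuts.items()}

        self.low_confidence_ = False
        if self.n_clusters is None:
            k, low = _elbow_from_curve(self.wss_curve_)
            self.k_ = k
            self.low_confidence_ = low
        else:
            self.k_ = int(self.n_clusters)
        if self.k_ in cuts:
            self.labels_ = cuts[self.k_]
        else:
            self.labels_ = hierarchy.fcluster(self.linkage_, self.k_, criterion="maxclust") - 1
        return self


def _elbow_from_curve(wss: dict[int, float]) -> tuple[int, bool]:
    """Largest second difference of WSS over the interior ks; ties -> smaller k.

    A curve whose strongest curvature explains less than a tenth of the
    total WSS drop (or no drop at all) yields k=2 with the low-confidence
    flag set.
    """
    ks = sorted(wss)
    interior = [k for k in ks if k - 1 in wss and k + 1 in wss and k >= 2]
    if not interior:
        return 2, True
    total_drop = wss[ks[0]] - wss[ks[-1]]
    if total_drop <= 0:
        return 2, True
    d2 = {k: (wss[k - 1] - wss[k]) - (wss[k] - wss[k + 1]) for k in interior}
    best = min(interior, key=lambda k: (-d2[k], k))
    low = d2[best] < _ELBOW_CONFIDENCE * total_drop
    return best, low


# ---------------------------------------------------------------------- #
# functional wrappers
# ---------------------------------------------------------------------- #
def cluster_matrix(matrix: TraitRelativeMatrix, k: int, k_max: int = 10) -> ClusterSolution:
    """Flat k-cluster solution of the matrix rows (Ward / Euclidean)."""
    n = matrix.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    est = TraitRelativeClustering(n_clusters=k, k_max=k_max).fit(matrix.values)
    return ClusterSolution(
        k=k,
        assignments={lab: int(c) for lab, c in zip(matrix.labels, est.labels_)},
        merge_tree=est.linkage_,
        wss_curve=est.wss_curve_,
        low_confidence=est.low_confidence_,
    )


def select_k_elbow(matrix: TraitRelativeMatrix, k_max: int = 10) -> ElbowResult:
    """Elbow-selected number of clusters for the matrix."""
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    est = TraitRelativeClustering(n_clusters=None, k_max=k_max).fit(matrix.values)
    return ElbowResult(k=est.k_, low_confidence=est.low_confidence_)


def quadrant_summary(matrix: TraitRelativeMatrix) -> pd.DataFrame:
    """Mean off-diagonal correlation for every role-pair quadrant.

    Returns a symmetric 3x3 frame over proband/sibling/parent; the
    diagonal cells summarise within-role (cross-trait) coherence.
    """
    roles = [role for _, role in matrix.labels]
    out = pd.DataFrame(np.nan, index=CLUSTER_ROLES, columns=CLUSTER_ROLES, dtype=float)
    for a in CLUSTER_ROLES:
        for b in CLUSTER_ROLES:
            vals = [
                matrix.values[i, j]
                for i in range(matrix.size) for j in range(matrix.size)
                if i != j and roles[i] == a and roles[j] == b
            ]
            if vals:
                out.loc[a, b] = float(np.mean(vals))
    return out


def merge_tree_text(matrix: TraitRelativeMatrix, solution: ClusterSolution) -> str:
    """Nested-parenthesis (newick-like) rendering of the merge tree."""
    tree = hierarchy.to_tree(solution.merge_tree)
    names = matrix.label_strings()

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        return f"({render(node.left)},{render(node.right)}):{node.dist:.6g}"

    return render(tree) + ";"


def planted_block_matrix(
    block_sizes: list[int], within_r: float = 0.8, between_r: float = 0.0,
    noise_sd: float = 0.0, seed: int | None = None,
) -> tuple[TraitRelativeMatrix, np.ndarray]:
    """Synthetic correlation matrix with planted block structure.

    Returns the matrix (with placeholder labels) and the true block
    assignment — the oracle for cluster-recovery tests.
    """
    n = sum(block_sizes)
    truth = np.concatenate([
        np.full(size, b) for b, size in enumerate(block_sizes)])
    values = np.full((n, n), float(between_r))
    for b in range(len(block_sizes)):
        idx = np.flatnonzero(truth == b)
        values[np.ix_(idx, idx)] = within_r
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        noise = (noise + noise.T) / 2.0
        values = values + noise
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    labels = [(f"t{i:02d}", CLUSTER_ROLES[i % 3]) for i in range(n)]
    return (
        TraitRelativeMatrix(labels=labels, values=values,
                            n_obs=np.full((n, n), 10_000, dtype=int)),
        truth,
    )
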
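"""Gene classification from simulator output.

Two complementary classifications:

* **Dyn-classes** — k-means on per-gene retention trajectories; classes are
  reported sorted by final-checkpoint centroid retention, descending, so
  class 1 is the most stable (typically the bulk of the transcriptome) and
  the last class decays fastest.
* **OXR-classes** — k-means on per-gene vectors of log2 retention ratios over
  consecutive overexpression factor pairs for one miRNA; every reported
  cluster must contain more than 5 genes (undersized clusters are dissolved
  and their genes reassigned to the nearest surviving centroid), and classes
  are sorted by size, descending.

k can be fixed or chosen by the elbow criterion on the explained-variance
fraction (between-cluster over total variance): the preferred k is where the
slope of the curve drops the most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .interactions import InteractionTable
from .screens import RetentionMatrix, consecutive_pairs
from .simulator import RetentionTrajectory

#: log2-ratio magnitude cap used when a retention hits zero.
LOG2_CAP = 10.0
#: k-means restarts; fixed seeding makes reruns identical.
KMEANS_RESTARTS = 10


@dataclass
class DynClassResult:
    """k-means partition of genes by retention-trajectory shape."""

    k: int
    assignment: dict[str, int]  # gene_id -> class label, 1-based
    centroids: pd.DataFrame  # classes x checkpoints
    class_sizes: list[int]
    mean_mbs_per_class: list[float] | None = None


@dataclass
class OXRClassResult:
    """k-means partition of genes by overexpression-ratio profile."""

    mirna_id: str
    k: int
    assignment: dict[str, int]
    centroids: pd.DataFrame  # classes x consecutive-pair axis (log2 ratios)
    class_sizes: list[int]


def _fit_kmeans(X: np.ndarray, k: int, seed: int = 0) -> KMeans:
    return KMeans(
        n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed
    ).fit(X)


def explained_variance_fraction(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster variance as a fraction of total variance."""
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total == 0:
        return 1.0
    within = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return 1.0 - within / total


def elbow_select_k(
    feature_matrix: np.ndarray | pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
) -> int:
    """Pick k at the elbow of the explained-variance curve.

    For each k the explained-variance fraction EVF(k) — between-cluster over
    total variance — is computed from a fixed-seed k-means fit; the chosen k
    maximizes the ratio of the marginal gain entering k to the gain leaving
    it, (EVF(k) - EVF(k-1)) / (EVF(k+1) - EVF(k) + eps): the point where the
    slope of the curve changes most sharply in relative terms. Degenerate
    input (all points identical) returns the smallest k with a warning.
    """
    X = np.asarray(feature_matrix, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError(
            f"k_range must lie within [2, n_points-1]; got {ks} for n={len(X)}"
        )
    if np.all(X == X[0]):
        warnings.warn("all points identical; returning smallest k",
                      stacklevel=2)
        return ks[0]
    # anchor the curve at k-1 and k+1 so the knee is defined at the endpoints
    grid = sorted({ks[0] - 1, *ks, ks[-1] + 1} & set(range(1, len(X) + 1)))
    evf = {k: explained_variance_fraction(X, _fit_kmeans(X, k, seed).labels_)
           for k in grid}
    eps = 1e-3  # floor on the outgoing gain, on the EVF scale of ~1
    best_k, best_ratio = ks[0], -np.inf
    for k in ks:
        gain_in = evf[k] - evf[k - 1]
        gain_out = evf.get(k + 1, evf[k]) - evf[k]
        ratio = gain_in / (gain_out + eps)
        if ratio > best_ratio + 1e-12:
            best_k, best_ratio = k, ratio
    return best_k


def dyn_classify(
    trajectory: RetentionTrajectory,
    k: int | str = 5,
    table: InteractionTable | None = None,
    seed: int = 0,
) -> DynClassResult:
    """Cluster genes by their retention trajectories (Dyn-classes).

    ``k`` may be an integer or ``"auto"`` (elbow selection). Classes are
    relabeled so centroid final retention strictly decreases with the class
    index: class 1 = most stable. If an interaction table is given, the mean
    number of binding sites per gene is reported per class.
    """
    X = trajectory.data.to_numpy(float)
    genes = trajectory.genes
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        k = elbow_select_k(X, range(2, min(11, len(genes))), seed=seed)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    if k == 1:
        labels = np.zeros(len(genes), dtype=int)
        centroids = X.mean(axis=0, keepdims=True)
    else:
        km = _fit_kmeans(X, k, seed)
        labels = km.labels_
        centroids = km.cluster_centers_
    # order classes by final-checkpoint centroid retention, descending
    order = np.argsort(-centroids[:, -1], kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    assignment = {g: relabel[int(c)] for g, c in zip(genes, labels)}
    cent = pd.DataFrame(
        centroids[order],
        index=pd.Index(range(1, k + 1), name="dyn_class"),
        columns=trajectory.data.columns,
    )
    sizes = [sum(1 for v in assignment.values() if v == c)
             for c in range(1, k + 1)]
    mean_mbs = None
    if table is not None:
        mean_mbs = []
        for c in range(1, k + 1):
            members = [g for g, v in assignment.items() if v == c]
            mean_mbs.append(
                float(np.mean([table.mbs_count_per_gene(g) for g in members]))
                if members
                else float("nan")
            )
    return DynClassResult(
        k=k, assignment=assignment, centroids=cent, class_sizes=sizes,
        mean_mbs_per_class=mean_mbs,
    )


def consecutive_ratio_profile(
    screens: Mapping[float, RetentionMatrix],
    mirna_id: str,
    factor_ladder: Sequence[float] | None = None,
    cap: float = LOG2_CAP,
) -> pd.DataFrame:
    """Per-gene log2 retention-ratio vectors over consecutive factor pairs.

    For the 7-step ladder this yields a 6-component vector per gene:
    log2(M_{f_{t+1}} / M_{f_t}) for the given miRNA's column, with zero
    retentions mapped to the +/-``cap`` sentinels (0/0 -> 0).
    """
    if factor_ladder is None:
        factor_ladder = sorted(screens)
    for f in factor_ladder:
        if f not in screens:
            raise KeyError(f"factor x{f:g} missing from screen results")
    pairs = consecutive_pairs(factor_ladder)
    cols = {}
    for hi, lo in pairs:
        num = screens[hi].data[mirna_id].to_numpy(float)
        den = screens[lo].data[mirna_id].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log2(num / den)
        v[(num == 0) & (den == 0)] = 0.0
        v[(num > 0) & (den == 0)] = cap
        v[(num == 0) & (den > 0)] = -cap
        cols[f"x{hi:g}/x{lo:g}"] = np.clip(v, -cap, cap)
    genes = screens[factor_ladder[0]].gene_order
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def oxr_classify(
    profiles: pd.DataFrame | Mapping[str, Sequence[float]],
    mirna_id: str = "",
    k: int | str = 5,
    min_cluster: int = 6,
    seed: int = 0,
) -> OXRClassResult:
    """Cluster genes by their consecutive-ratio profiles (OXR-classes).

    Clusters with fewer than ``min_cluster`` genes (default: the >5-gene
    rule) are dissolved and their genes reassigned to the nearest surviving
    centroid. Classes are sorted by size, descending, so class 1 is the
    dominant, dosage-indifferent bulk.
    """
    df = (
        profiles
        if isinstance(profiles, pd.DataFrame)
        else pd.DataFrame.from_dict(dict(profiles), orient="index")
    )
    X = df.to_numpy(float)
    genes = list(df.index)
    if len(genes) < min_cluster:
        raise ValueError(
            f"need >= {min_cluster} genes, got {len(genes)}"
        )
    if isinstance(k, str):
        if k != "auto":
            raise ValueError(f"k must be an integer or 'auto', got {k!r}")
        k = elbow_select_k(X, range(2, min(11, len(genes))), seed=seed)
    km = _fit_kmeans(X, k, seed)
    labels = km.labels_.copy()
    centroids = km.cluster_centers_
    sizes = np.bincount(labels, minlength=k)
    surviving = np.flatnonzero(sizes >= min_cluster)
    if surviving.size == 0:
        raise ValueError(
            f"all {k} clusters have < {min_cluster} genes; nothing survives"
        )
    if surviving.size < k:
        # dissolve undersized clusters, reassign to nearest surviving centroid
        doomed = np.isin(labels, surviving, invert=True)
        d = np.linalg.norm(
            X[doomed, None, :] - centroids[None, surviving, :], axis=2
        )
        labels[doomed] = surviving[np.argmin(d, axis=1)]
    # recompute centroids and order classes by size, descending
    final_sizes = {c: int((labels == c).sum()) for c in surviving}
    order = sorted(surviving, key=lambda c: (-final_sizes[c], c))
    relabel = {int(c): rank + 1 for rank, c in enumerate(order)}
    assignment = {g: relabel[int(c)] for g, c in zip(genes, labels)}
    cent_rows = [X[labels == c].mean(axis=0) for c in order]
    cent = pd.DataFrame(
        cent_rows,
        index=pd.Index(range(1, len(order) + 1), name="oxr_class"),
        columns=df.columns,
    )
    return OXRClassResult(
        mirna_id=mirna_id,
        k=len(order),
        assignment=assignment,
        centroids=cent,
        class_sizes=[final_sizes[c] for c in order],
    )
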
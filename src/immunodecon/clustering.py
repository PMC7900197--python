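"""Immune-pattern discovery over cell-family fractions.

K-means (Lloyd, multiple seeded restarts) clusters samples by their family
fractions; the number of clusters is chosen by the elbow (knee) of the
inertia-vs-k curve, located as the point of maximum perpendicular distance
to the chord joining the curve's endpoints. Clusters are named by the
ordering of their CD4 T / CD8 T / macrophage centroid fractions (e.g.
"CD4<MPhi<CD8"), with "~" marking fractions closer than a tolerance tau.

Also provides the descriptive structure operations used alongside the
clustering: the pairwise Pearson correlation map of family fractions and
an agglomerative (average-linkage, correlation-distance) dendrogram of the
families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datatypes import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ImmuneClassModel",
    "kmeans_fit",
    "select_k_elbow",
    "name_clusters",
    "celltype_correlation",
    "hierarchical_cluster_celltypes",
    "dendrogram_to_newick",
    "FOCAL_FAMILIES",
]

# focal families whose centroid ordering names each immune pattern;
# symbol order here is also the display order inside an "approximately
# equal" group (the field writes CD4<CD8≈MΦ, not CD4<MΦ≈CD8)
FOCAL_FAMILIES = {"CD4": "CD4 T cells", "CD8": "CD8 T cells", "MΦ": "Macrophages"}


@dataclass
class ImmuneClassModel:
    """A fitted K-means immune-class model.

    ``labels`` are 1-based cluster ids per sample; ``centroids`` is a
    clusters x families frame; ``inertia_profile`` maps each candidate k to
    its best-restart inertia (only the fitted k when no elbow search ran).
    """

    k: int
    centroids: pd.DataFrame
    labels: pd.Series
    inertia_profile: dict[int, float]
    seed: int
    archetype_names: Optional[dict[int, str]] = field(default=None)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        lab = set(self.labels.unique())
        if not lab <= set(range(1, self.k + 1)):
            raise ValidationError("labels must lie in 1..k")
        if len(lab) != self.k:
            raise ValidationError("every cluster must be non-empty")
        ks = sorted(self.inertia_profile)
        vals = [self.inertia_profile[k] for k in ks]
        if any(v < 0 for v in vals):
            raise ValidationError("inertia must be non-negative")
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValidationError("inertia profile must be non-increasing in k")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "families": list(self.centroids.columns),
            "centroids": self.centroids.to_numpy().tolist(),
            "sample_ids": [str(s) for s in self.labels.index],
            "labels": [int(l) for l in self.labels],
            "inertia_profile": {str(k): v for k, v in self.inertia_profile.items()},
            "archetype_names": (
                {str(k): v for k, v in self.archetype_names.items()}
                if self.archetype_names
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImmuneClassModel":
        labels = pd.Series(
            [int(l) for l in d["labels"]], index=d["sample_ids"], name="cluster"
        )
        labels.index.name = "sample_id"
        return cls(
            k=int(d["k"]),
            centroids=pd.DataFrame(
                d["centroids"],
                index=range(1, int(d["k"]) + 1),
                columns=d["families"],
            ),
            labels=labels,
            inertia_profile={int(k): float(v) for k, v in d["inertia_profile"].items()},
            seed=int(d["seed"]),
            archetype_names=(
                {int(k): v for k, v in d["archetype_names"].items()}
                if d.get("archetype_names")
                else None
            ),
        )


def kmeans_fit(
    fractions: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    inertia_profile: Optional[dict[int, float]] = None,
) -> ImmuneClassModel:
    """Fit K-means with ``n_restarts`` seeded initializations, keep the best.

    Features are the raw family fractions: they are already commensurate
    (each in [0,1], rows summing to 1), so no re-standardization is applied.
    """
    if fractions.isna().to_numpy().any():
        raise ValidationError("fractions contain missing values")
    n = fractions.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k must lie in 1..{n}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    km.fit(fractions.to_numpy())
    labels = pd.Series(
        (km.labels_ + 1).astype(np.int64), index=fractions.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=fractions.columns
    )
    profile = dict(inertia_profile) if inertia_profile else {}
    profile[k] = float(km.inertia_)
    return ImmuneClassModel(
        k=k, centroids=centroids, labels=labels,
        inertia_profile=profile, seed=seed,
    )


def select_k_elbow(
    fractions: pd.DataFrame,
    k_range: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, dict[int, float]]:
    """Pick k at the knee of the inertia curve.

    Fits K-means for every k in the (contiguous, ascending) range and
    returns the k whose (k, inertia) point has the maximum perpendicular
    distance to the chord joining the first and last profile points. Ties
    break toward the smallest k (parsimony).
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValidationError("k_range needs at least 3 values to locate a knee")
    if ks != list(range(ks[0], ks[-1] + 1)) or ks[0] < 1:
        raise ValidationError("k_range must be contiguous ascending with min >= 1")
    profile: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                    algorithm="lloyd")
        km.fit(fractions.to_numpy())
        profile[k] = float(km.inertia_)
    pts = np.array([[float(k), profile[k]] for k in ks])
    chord = pts[-1] - pts[0]
    norm = np.linalg.norm(chord)
    if norm == 0:
        return ks[0], profile
    chord = chord / norm
    rel = pts - pts[0]
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    # strict '>' keeps the earliest maximizer: ties break to smallest k
    best_i = int(np.argmax(dist))
    return ks[best_i], profile


def name_clusters(model: ImmuneClassModel, tau: float = 0.02) -> dict[int, str]:
    """Name each cluster by the ordering of its focal centroid fractions.

    Orders the CD4 T, CD8 T and macrophage centroid fractions ascending and
    joins consecutive symbols with ``<``, or ``≈`` when they differ by less
    than ``tau`` (absolute fraction). Within a run of ``≈``-tied symbols
    the display order is the conventional CD4, CD8, MΦ. Names depend only
    on centroid values, so they are invariant to cluster index permutation.
    """
    missing = [f for f in FOCAL_FAMILIES.values() if f not in model.centroids.columns]
    if missing:
        raise ValidationError(f"centroids missing focal families: {missing}")
    precedence = {sym: i for i, sym in enumerate(FOCAL_FAMILIES)}
    names = {}
    for cid in model.centroids.index:
        vals = sorted(
            (float(model.centroids.loc[cid, fam]), precedence[sym], sym)
            for sym, fam in FOCAL_FAMILIES.items()
        )
        # group symbols chained by |diff| < tau between consecutive values
        groups: list[list[tuple[float, int, str]]] = [[vals[0]]]
        for prev, cur in zip(vals, vals[1:]):
            if abs(cur[0] - prev[0]) < tau:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        rendered = [
            "≈".join(sym for _, _, sym in sorted(g, key=lambda t: t[1]))
            for g in groups
        ]
        names[int(cid)] = "<".join(rendered)
    return names


def celltype_correlation(fractions: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of family fractions across samples.

    Zero-variance families get missing (NaN) correlations; the diagonal is
    1 for families with variance.
    """
    if fractions.shape[0] < 3:
        raise ValidationError("need at least 3 samples for a correlation map")
    corr = fractions.corr(method="pearson")
    zero_var = fractions.std(ddof=0) == 0
    if zero_var.any():
        logger.warning(
            "zero-variance families, correlations reported missing: %s",
            list(fractions.columns[zero_var]),
        )
        corr.loc[zero_var, :] = np.nan
        corr.loc[:, zero_var] = np.nan
    return corr


def hierarchical_cluster_celltypes(
    fractions: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of families with 1 - Pearson distance.

    Zero-variance families are excluded with a warning. Returns the scipy
    linkage matrix and the leaf order (family names).
    """
    zero_var = fractions.std(ddof=0) == 0
    if zero_var.any():
        logger.warning(
            "excluding zero-variance families from dendrogram: %s",
            list(fractions.columns[zero_var]),
        )
        fractions = fractions.loc[:, ~zero_var]
    families = list(fractions.columns)
    if len(families) < 2:
        raise ValidationError("need at least 2 families with variance")
    corr = fractions.corr(method="pearson").to_numpy()
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return linkage, families


def dendrogram_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def escape(name: str) -> str:
        return "'" + name.replace("'", "''") + "'" if any(
            c in name for c in " (),:;'"
        ) else name

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{escape(leaf_names[node.id])}:{parent_height - 0.0:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = walk(tree, tree.dist)
    # root branch length is meaningless; strip it
    body = body.rsplit(":", 1)[0]
    return body + ";"
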
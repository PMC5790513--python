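"""Two-group tumor phenotyping by K-means on seed-gene expression.

Tumors (samples) are the clustered objects and seed genes the feature
dimensions; expression must already be log2-transformed and per-gene
median-centered. The partition with the lowest within-cluster sum of squares
over many random restarts is kept, and the cluster over-expressing the seed
genes is labeled the high-hypoxia phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import ValidationError


@dataclass
class PhenotypeAssignment:
    """K-means result: per-sample cluster index and (after labeling) the
    high/low-hypoxia phenotype label."""

    cluster: pd.Series
    cluster_inertia: float
    n_restarts_used: int
    seed_gene_ids: list[str]
    labels: pd.Series | None = None

    @property
    def group_sizes(self) -> pd.Series:
        key = self.labels if self.labels is not None else self.cluster
        return key.value_counts()

    def write_csv(self, path) -> None:
        if self.labels is None:
            raise ValidationError("clusters have not been labeled yet")
        out = self.labels.rename("phenotype").to_frame()
        out.index.name = "sample_id"
        out.to_csv(path)


def kmeans_two_group(expr_seed: pd.DataFrame, n_restarts: int = 1000,
                     seed: int | None = 0) -> PhenotypeAssignment:
    """Best-of-``n_restarts`` Lloyd K-means with k = 2 on sample vectors.

    ``expr_seed`` is seed-genes x samples, already median-centered.
    Deterministic under ``seed``. Degenerate inputs (fewer than two distinct
    sample profiles) raise.
    """
    if expr_seed.shape[1] < 2:
        raise ValidationError("need at least two samples to form two clusters")
    if expr_seed.shape[0] < 1:
        raise ValidationError("need at least one seed gene")
    X = expr_seed.to_numpy(dtype=float).T  # samples x genes
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValidationError(
            "all samples identical: two non-empty clusters are impossible"
        )
    km = KMeans(n_clusters=2, n_init=n_restarts, init="random",
                algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(X)
    if len(np.unique(labels)) < 2:
        raise ValidationError("K-means produced an empty cluster")
    cluster = pd.Series(labels, index=expr_seed.columns, name="cluster")
    return PhenotypeAssignment(
        cluster=cluster,
        cluster_inertia=float(km.inertia_),
        n_restarts_used=n_restarts,
        seed_gene_ids=list(expr_seed.index),
    )


def label_clusters(assignment: PhenotypeAssignment,
                   expr_seed: pd.DataFrame) -> PhenotypeAssignment:
    """Label the cluster with the larger mean seed-gene expression ``high``.

    The mean is taken over all seed genes and member samples of each cluster
    on the centered scale; an exact tie falls to the cluster of the first
    sample (deterministic, with a warning).
    """
    means = {}
    for c in sorted(assignment.cluster.unique()):
        cols = assignment.cluster.index[assignment.cluster == c]
        means[c] = float(expr_seed[cols].to_numpy().mean())
    ordered = sorted(means)
    if len(ordered) != 2:
        raise ValidationError("exactly two clusters required for labeling")
    a, b = ordered
    if means[a] == means[b]:
        import warnings

        warnings.warn("exact tie in cluster means; first sample's cluster "
                      "labeled high", stacklevel=2)
        high = assignment.cluster.iloc[0]
    else:
        high = a if means[a] > means[b] else b
    labels = assignment.cluster.map(lambda c: "high" if c == high else "low")
    return PhenotypeAssignment(
        cluster=assignment.cluster,
        cluster_inertia=assignment.cluster_inertia,
        n_restarts_used=assignment.n_restarts_used,
        seed_gene_ids=assignment.seed_gene_ids,
        labels=labels.rename("phenotype"),
    )


def cluster_phenotypes(expr_seed: pd.DataFrame, n_restarts: int = 1000,
                       seed: int | None = 0) -> PhenotypeAssignment:
    """Convenience wrapper: cluster then label in one call."""
    return label_clusters(kmeans_two_group(expr_seed, n_restarts, seed), expr_seed)
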
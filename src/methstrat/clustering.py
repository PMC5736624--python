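"""Variable-probe selection and Ward clustering of methylation profiles.

Samples are partitioned by agglomerative clustering under Ward's
minimum-variance criterion on Euclidean distances between beta-value
profiles, restricted to the most variable probes.  The resulting clusters
are ranked by mean methylation and named low / intermediate / high (for
k = 3; rank names otherwise), mirroring the usual presentation of
methylation subgroups in leukemia cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterModel",
    "select_variable_probes",
    "ward_cluster",
    "order_clusters",
    "fit_cluster_model",
]

RANK_NAMES_3 = ("low", "intermediate", "high")


def select_variable_probes(
    beta: pd.DataFrame,
    sd_threshold: float = 0.25,
    top_fraction: float | None = None,
) -> list:
    """Select the most variable probes across samples.

    Default mode returns probes whose across-sample standard deviation
    (n - 1 denominator) exceeds ``sd_threshold``, ordered by descending SD.
    When ``top_fraction`` is given it takes precedence and the
    ``ceil(top_fraction * n_probes)`` highest-SD probes are returned instead.

    Ties in SD are broken by probe order in the input, which makes the
    selection deterministic.
    """
    if beta.shape[1] < 2:
        raise ValueError("at least two samples are required to compute SDs")
    sd = beta.std(axis=1, ddof=1)
    # stable sort keeps input order among exact ties
    order = sd.sort_values(ascending=False, kind="stable")
    if top_fraction is not None:
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        n = math.ceil(top_fraction * beta.shape[0])
        return list(order.index[:n])
    return list(order.index[order.to_numpy() > sd_threshold])


def ward_cluster(beta_subset: pd.DataFrame, k: int = 3):
    """Ward's minimum-variance clustering of samples on beta profiles.

    Parameters
    ----------
    beta_subset
        Probes x samples matrix restricted to the signature probes.
    k
        Number of clusters to cut the tree into.

    Returns
    -------
    labels : pandas.Series
        Integer cluster label (0..k-1) per sample, indexed by sample id.
        Label numbering follows scipy's ``fcluster`` output shifted to
        0-based; it is arbitrary until :func:`order_clusters` ranks it.
    linkage_matrix : numpy.ndarray
        The (n-1) x 4 merge history (scipy linkage format); merge heights
        are non-decreasing under Ward's criterion.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = beta_subset.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples ({n})")
    X = beta_subset.to_numpy(dtype=float).T  # samples x probes
    if n == 1:
        return pd.Series([0], index=beta_subset.columns), np.empty((0, 4))
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust") - 1
    return pd.Series(raw, index=beta_subset.columns), Z


def order_clusters(beta_subset: pd.DataFrame, labels: pd.Series) -> dict:
    """Rank clusters by mean methylation and attach low→high names.

    Each cluster's score is the mean beta over all its samples and all
    signature probes; the lowest-scoring cluster is named ``low``.  Exact
    ties are broken by the original (smaller) cluster label taking the lower
    rank.  For k != 3 clusters are named ``rank1`` (lowest) upward.

    Returns a mapping from original cluster label to rank name.
    """
    uniq = sorted(pd.unique(labels))
    means = {
        lab: float(beta_subset.loc[:, labels.index[labels == lab]].to_numpy().mean())
        for lab in uniq
    }
    ranked = sorted(uniq, key=lambda lab: (means[lab], lab))
    if len(uniq) == 3:
        names = RANK_NAMES_3
    else:
        names = tuple(f"rank{i + 1}" for i in range(len(uniq)))
    return {lab: names[i] for i, lab in enumerate(ranked)}


@dataclass
class ClusterModel:
    """A fitted methylation cluster model.

    Attributes
    ----------
    signature_probes : list
        Probe ids used for clustering, ordered by descending variability.
    labels : pandas.Series
        Ordered cluster name (e.g. low/intermediate/high) per sample.
    centroids : pandas.DataFrame
        Signature-probes x clusters matrix of mean beta per cluster.
    linkage_matrix : numpy.ndarray
        Scipy-format merge history of the sample dendrogram.
    k : int
        Number of clusters.
    """

    signature_probes: list
    labels: pd.Series
    centroids: pd.DataFrame
    linkage_matrix: np.ndarray = field(repr=False)
    k: int = 3

    @property
    def cluster_names(self) -> list:
        return list(self.centroids.columns)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "signature_probes": [str(p) for p in self.signature_probes],
            "labels": {str(s): str(l) for s, l in self.labels.items()},
            "centroids": {
                str(c): [float(v) for v in self.centroids[c]]
                for c in self.centroids.columns
            },
            "linkage": self.linkage_matrix.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        probes = payload["signature_probes"]
        centroids = pd.DataFrame(
            {c: vals for c, vals in payload["centroids"].items()}, index=probes
        )
        labels = pd.Series(payload["labels"])
        return cls(
            signature_probes=probes,
            labels=labels,
            centroids=centroids,
            linkage_matrix=np.asarray(payload["linkage"], dtype=float),
            k=int(payload["k"]),
        )


def fit_cluster_model(
    beta: pd.DataFrame,
    sd_threshold: float = 0.25,
    top_fraction: float | None = None,
    k: int = 3,
) -> ClusterModel:
    """Select variable probes, Ward-cluster samples, and order the clusters.

    Convenience wrapper running the discovery-cohort procedure end to end:
    probe selection, Ward clustering to ``k`` groups, low→high ordering and
    per-cluster centroid computation (arithmetic mean beta per probe).
    """
    from .classification import compute_centroids

    probes = select_variable_probes(beta, sd_threshold=sd_threshold,
                                    top_fraction=top_fraction)
    if len(probes) == 0:
        raise ValueError("no probes passed the variability selection")
    sub = beta.loc[probes]
    raw_labels, Z = ward_cluster(sub, k=k)
    ordering = order_clusters(sub, raw_labels)
    labels = raw_labels.map(ordering)
    centroids = compute_centroids(sub, labels)
    if k == 3:
        centroids = centroids[[n for n in RANK_NAMES_3 if n in centroids.columns]]
    return ClusterModel(
        signature_probes=list(probes),
        labels=labels,
        centroids=centroids,
        linkage_matrix=Z,
        k=k,
    )
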
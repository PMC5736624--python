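"""Nearest-centroid classification and CpG signature distillation.

An independent cohort is assigned to the discovery clusters by minimum
Euclidean distance to the discovery centroids.  The distillation procedure
then asks how few probes suffice: probes are ranked from most to least
"typical" (smallest summed squared deviation of samples from their own
cluster centroid), and the validation cohort is re-classified with the top
k probes for k on a grid, counting disagreements with the full-signature
calls as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_centroids",
    "classify_nearest_centroid",
    "rank_probe_typicality",
    "distill_signature",
    "DistillationCurve",
]


def compute_centroids(beta_subset: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster centroid: arithmetic mean beta per probe over members.

    Returns a probes x clusters DataFrame; raises on an empty cluster.
    """
    labels = labels.reindex(beta_subset.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a cluster label")
    cols = {}
    for lab in pd.unique(labels):
        members = labels.index[labels == lab]
        if len(members) == 0:
            raise ValueError(f"cluster {lab!r} is empty")
        cols[lab] = beta_subset[members].mean(axis=1)
    return pd.DataFrame(cols)


def _order_clusters_low_first(centroids: pd.DataFrame) -> list:
    """Cluster names ordered by ascending mean centroid methylation.

    Used for the classification tie-break: an equidistant sample goes to the
    lower-methylation cluster.  The canonical low/intermediate/high names
    sort this way by construction, but arbitrary names are handled too.
    """
    means = centroids.mean(axis=0)
    return list(means.sort_values(kind="stable").index)


def classify_nearest_centroid(
    samples: pd.DataFrame, centroids: pd.DataFrame
) -> pd.DataFrame:
    """Assign each sample to the cluster with the nearest centroid.

    Parameters
    ----------
    samples
        Probes x samples beta matrix; its probe set must exactly match the
        centroid probe set (order is normalized by id).
    centroids
        Probes x clusters centroid matrix.

    Returns
    -------
    pandas.DataFrame
        Indexed by sample id with columns ``label`` (assigned cluster) and
        ``distance`` (Euclidean distance to the winning centroid).  Exact
        distance ties go to the lower-methylation cluster.
    """
    missing = centroids.index.difference(samples.index)
    extra = samples.index.difference(centroids.index)
    if len(missing) or len(extra):
        raise KeyError(
            f"probe set mismatch: missing={list(map(str, missing[:5]))} "
            f"extra={list(map(str, extra[:5]))}"
        )
    samples = samples.loc[centroids.index]

    order = _order_clusters_low_first(centroids)
    C = centroids[order].to_numpy(dtype=float)          # probes x clusters
    X = samples.to_numpy(dtype=float)                   # probes x samples
    # squared distances: clusters x samples
    d2 = ((X[:, None, :] - C[:, :, None]) ** 2).sum(axis=0)
    # argmin over clusters; ties resolve to the first (lowest-methylation)
    win = np.argmin(d2, axis=0)
    dist = np.sqrt(d2[win, np.arange(d2.shape[1])])
    labels = [order[w] for w in win]
    return pd.DataFrame(
        {"label": labels, "distance": dist}, index=samples.columns
    )


def rank_probe_typicality(
    beta_subset: pd.DataFrame,
    labels: pd.Series,
    centroids: pd.DataFrame | None = None,
) -> pd.Series:
    """Rank probes from most to least typical of their cluster structure.

    A probe's score is the squared deviation of each sample's beta from the
    centroid of that sample's cluster, summed over all samples; small scores
    mean the probe tracks its cluster means tightly.  Returns scores ordered
    ascending (most typical first); exact ties are broken by probe id.
    """
    if centroids is None:
        centroids = compute_centroids(beta_subset, labels)
    labels = labels.reindex(beta_subset.columns)
    expected = centroids.loc[beta_subset.index, labels.to_numpy()].to_numpy()
    resid = beta_subset.to_numpy(dtype=float) - expected
    scores = pd.Series((resid ** 2).sum(axis=1), index=beta_subset.index)
    key = pd.DataFrame({"score": scores, "probe": scores.index.astype(str)})
    key = key.sort_values(["score", "probe"], kind="stable")
    return scores.loc[key.index]


@dataclass
class DistillationCurve:
    """Classification-error curve over shrinking signature sizes.

    Attributes
    ----------
    ranked_probes : list
        Probes ordered most → least typical on the discovery cohort.
    k_grid : list of int
        Signature sizes evaluated (strictly increasing).
    errors : list of int
        Number of validation samples whose top-k call disagrees with the
        full-signature call, per k.
    reference_calls : pandas.Series
        Full-signature nearest-centroid calls for the validation cohort.
    tolerance : int
        Error count treated as "recapitulating" the clusters.
    """

    ranked_probes: list
    k_grid: list
    errors: list
    reference_calls: pd.Series
    tolerance: int = 1

    @property
    def min_recapitulating_k(self) -> int | None:
        """Smallest k whose error count is within tolerance (None if none)."""
        for k, e in zip(self.k_grid, self.errors):
            if e <= self.tolerance:
                return k
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_grid, "errors": self.errors})


def distill_signature(
    discovery_beta: pd.DataFrame,
    discovery_labels: pd.Series,
    validation_beta: pd.DataFrame,
    k_min: int = 5,
    k_max: int = 200,
    step: int = 5,
    tolerance: int = 1,
) -> DistillationCurve:
    """Find how few typical probes recapitulate the full-signature calls.

    Probes are ranked by typicality on the discovery cohort; for each k in
    ``range(k_min, k_max + 1, step)`` (truncated at the signature size, plus
    the full size itself as the final grid point when it is not covered) the
    validation cohort is classified with the top-k probes — centroids
    restricted to those probes — and disagreements with the full-signature
    calls are counted as errors.

    ``discovery_beta`` and ``validation_beta`` are probes x samples matrices
    over the same signature probes (validation must cover all of them).
    """
    centroids = compute_centroids(discovery_beta, discovery_labels)
    missing = discovery_beta.index.difference(validation_beta.index)
    if len(missing):
        raise KeyError(
            "validation matrix missing signature probes: "
            + ", ".join(map(str, missing[:5]))
        )
    validation_beta = validation_beta.loc[discovery_beta.index]

    scores = rank_probe_typicality(discovery_beta, discovery_labels, centroids)
    ranked = list(scores.index)
    n_sig = len(ranked)

    reference = classify_nearest_centroid(validation_beta, centroids)["label"]

    k_grid = [k for k in range(k_min, k_max + 1, step) if k <= n_sig]
    if not k_grid or k_grid[-1] < min(k_max, n_sig):
        # grid truncated by the signature size: evaluate the full signature too
        if n_sig <= k_max and n_sig not in k_grid:
            k_grid.append(n_sig)

    errors = []
    for k in k_grid:
        top = ranked[:k]
        calls = classify_nearest_centroid(
            validation_beta.loc[top], centroids.loc[top]
        )["label"]
        errors.append(int((calls != reference).sum()))

    return DistillationCurve(
        ranked_probes=ranked,
        k_grid=k_grid,
        errors=errors,
        reference_calls=reference,
        tolerance=tolerance,
    )
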
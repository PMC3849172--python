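"""Unsupervised hierarchical clustering and SVM leave-one-out confirmation.

Samples (or genes) are clustered with correlation distance
(1 − Pearson r between item profiles) and average linkage — the de-facto
convention of expression-signature studies — and the two dominant clusters
are obtained by removing the final merge. A linear soft-margin SVM under
leave-one-out cross-validation confirms a known binary split (e.g. malignant
vs premalignant) and names the misclassified samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.svm import SVC

from .errors import DataError
from .io import ExpressionMatrix

AXIS_SAMPLES = "samples"
AXIS_GENES = "genes"


@dataclass
class Dendrogram:
    """An agglomerative clustering tree in scipy linkage form.

    ``merges`` is the (n−1) × 4 scipy linkage matrix over ``labels``;
    merge heights are nondecreasing for average linkage.
    """

    merges: np.ndarray
    labels: list[str]
    linkage_method: str = "average"
    distance: str = "pearson"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram display order."""
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


@dataclass
class ClusterAssignment:
    """A two-group partition of clustered items."""

    labels: pd.Series  # item -> 1 | 2
    criterion: str = "remove-final-merge"

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


@dataclass
class SvmLoocvResult:
    accuracy: float
    predictions: pd.Series  # sample -> predicted label
    misclassified: list[str] = field(default_factory=list)


def correlation_distance(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 − Pearson distance between the rows of ``profiles``.

    Raises :class:`DataError` naming the first zero-variance item, for which
    correlation is undefined.
    """
    values = profiles.values.astype(float)
    sd = values.std(axis=1)
    flat = np.flatnonzero(~(sd > 0))
    if len(flat):
        raise DataError(
            f"correlation undefined for zero-variance item {profiles.index[flat[0]]!r}"
        )
    corr = np.corrcoef(values)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry so squareform accepts floating-point output
    return (dist + dist.T) / 2.0


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    probe_ids=None,
    axis: str = AXIS_SAMPLES,
    linkage_method: str = "average",
) -> Dendrogram:
    """Cluster samples or genes over a probe subset with correlation distance."""
    sub = matrix if probe_ids is None else matrix.restrict(probes=probe_ids)
    if axis == AXIS_SAMPLES:
        profiles = sub.values.T
    elif axis == AXIS_GENES:
        profiles = sub.values
    else:
        raise DataError(f"axis must be '{AXIS_SAMPLES}' or '{AXIS_GENES}' (got {axis!r})")
    if profiles.shape[0] < 2:
        raise DataError(f"need >= 2 items to cluster (got {profiles.shape[0]})")
    if profiles.shape[1] < 2:
        raise DataError(f"need >= 2 probes to cluster (got {profiles.shape[1]})")
    dist = correlation_distance(profiles)
    merges = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return Dendrogram(merges=merges, labels=list(profiles.index), linkage_method=linkage_method)


def cut_two(dendrogram: Dendrogram) -> ClusterAssignment:
    """Partition into the two dominant clusters by removing the final merge.

    Cluster 1 is the cluster containing the first leaf, for a deterministic
    labeling.
    """
    if dendrogram.n_leaves < 2:
        raise DataError("need >= 2 leaves to cut into two clusters")
    flat = hierarchy.fcluster(dendrogram.merges, t=2, criterion="maxclust")
    if len(set(flat)) != 2:  # pathological all-zero-height tree; split final merge manually
        raise DataError("could not split dendrogram into two nonempty clusters")
    if flat[0] != 1:
        flat = 3 - flat
    return ClusterAssignment(labels=pd.Series(flat, index=dendrogram.labels))


def svm_loocv(
    matrix,
    labels: pd.Series,
    probe_ids=None,
    C: float = 1.0,
) -> SvmLoocvResult:
    """Leave-one-out linear-SVM confirmation of a binary sample split.

    ``matrix`` may be an :class:`ExpressionMatrix` or a samples × features
    DataFrame. Each sample is predicted by a linear soft-margin SVM trained
    on all others; both classes must have at least two members.
    """
    if isinstance(matrix, ExpressionMatrix):
        sub = matrix if probe_ids is None else matrix.restrict(probes=probe_ids)
        X = sub.values.T
    else:
        X = matrix if probe_ids is None else matrix[list(probe_ids)]
    labels = labels.reindex(X.index)
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise DataError(
            f"svm_loocv requires two classes with >= 2 members each (got {counts.to_dict()})"
        )
    Xv = X.values.astype(float)
    yv = labels.values
    preds = []
    for i in range(len(yv)):
        keep = np.arange(len(yv)) != i
        model = SVC(kernel="linear", C=C)
        model.fit(Xv[keep], yv[keep])
        preds.append(model.predict(Xv[i : i + 1])[0])
    predictions = pd.Series(preds, index=X.index)
    correct = predictions.values == yv
    misclassified = list(predictions.index[~correct])
    return SvmLoocvResult(
        accuracy=float(correct.mean()), predictions=predictions, misclassified=misclassified
    )


__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "SvmLoocvResult",
    "correlation_distance",
    "hierarchical_cluster",
    "cut_two",
    "svm_loocv",
    "AXIS_SAMPLES",
    "AXIS_GENES",
]
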
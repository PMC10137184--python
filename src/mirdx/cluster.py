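"""Unsupervised two-group hierarchical clustering of samples and its evaluation.

Samples are clustered on the marker submatrix using Manhattan distance with
Ward's minimum-variance linkage applied directly to the Manhattan
dissimilarities (the classic ``ward.D`` behavior).  SciPy's ``ward`` updates
squared dissimilarities through the Lance–Williams recurrence, so feeding it
the square roots of the Manhattan distances reproduces that merge order
exactly.  The tree is cut into exactly two clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Two-cluster sample partition plus the merge history."""

    clusters: pd.Series  # sample_id -> 1 | 2
    linkage_record: np.ndarray  # scipy linkage matrix


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and derived rates (tumor = positive class)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy}


def hcluster_two(matrix: pd.DataFrame, markers: pd.DataFrame | list | None = None
                 ) -> ClusterAssignment:
    """Cluster samples into two groups on the marker submatrix.

    ``markers`` may be a marker table (indexed by feature_id), a plain list of
    feature ids, or None (use all features).  Requested features missing from
    the matrix are dropped with a warning.
    """
    if markers is None:
        feats = matrix.index
    else:
        wanted = markers.index if isinstance(markers, pd.DataFrame) else pd.Index(markers)
        feats = wanted.intersection(matrix.index)
        missing = wanted.difference(matrix.index)
        if len(missing):
            log.warning("dropping %d marker(s) absent from matrix: %s",
                        len(missing), missing.tolist()[:10])
        if len(feats) == 0:
            raise ValidationError("no requested features present in matrix")
    sub = matrix.loc[feats]
    if sub.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 samples")
    dist = pdist(sub.to_numpy(float).T, metric="cityblock")
    # sqrt trick: scipy ward squares its input inside Lance-Williams,
    # so sqrt(D) gives ward.D merge order on the Manhattan distances D
    Z = linkage(np.sqrt(dist), method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    clusters = pd.Series(labels, index=sub.columns, name="cluster")
    return ClusterAssignment(clusters=clusters, linkage_record=Z)


def evaluate_clusters(assignment: ClusterAssignment, truth: pd.Series | pd.DataFrame
                      ) -> ClassificationReport:
    """Score a two-cluster partition against true tumor/normal labels.

    Each cluster takes the majority true class of its members (ties labelled
    tumor), then a standard confusion report is computed.
    """
    if isinstance(truth, pd.DataFrame):
        truth = truth["class_label"]
    missing = assignment.clusters.index.difference(truth.dropna().index)
    if len(missing):
        raise ValidationError(f"truth missing for sample(s): {missing.tolist()[:5]}")
    truth = truth.loc[assignment.clusters.index]
    cluster_label = {}
    for c in (1, 2):
        members = truth[assignment.clusters == c]
        n_t = int((members == "tumor").sum())
        n_n = int((members == "normal").sum())
        cluster_label[c] = "tumor" if n_t >= n_n else "normal"
    predicted = assignment.clusters.map(cluster_label)
    return confusion_report(predicted, truth)


def confusion_report(predicted: pd.Series, truth: pd.Series) -> ClassificationReport:
    """Confusion report with tumor as the positive class."""
    predicted, truth = predicted.align(truth, join="inner")
    tp = int(((predicted == "tumor") & (truth == "tumor")).sum())
    fn = int(((predicted == "normal") & (truth == "tumor")).sum())
    tn = int(((predicted == "normal") & (truth == "normal")).sum())
    fp = int(((predicted == "tumor") & (truth == "normal")).sum())
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp)
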
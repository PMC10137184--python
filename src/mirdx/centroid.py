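"""Nearest-centroid tumor/normal classifier robust to partial feature overlap.

The tumor and normal centroids are per-feature means of log2 expression over
the training classes.  A test sample is correlated (Pearson) with each
centroid over the intersected feature set and assigned to the class with the
larger correlation; ties go to tumor (flagged) — in a screening context the
sensitive call is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClassificationReport, confusion_report
from .errors import ValidationError

MIN_OVERLAP = 3


@dataclass
class CentroidModel:
    """Class centroids aligned on a common marker feature list."""

    feature_ids: list[str]
    tumor_centroid: np.ndarray
    normal_centroid: np.ndarray
    training_provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tumor_centroid": self.tumor_centroid,
                             "normal_centroid": self.normal_centroid},
                            index=pd.Index(self.feature_ids, name="feature_id"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "CentroidModel":
        return cls(feature_ids=df.index.astype(str).tolist(),
                   tumor_centroid=df["tumor_centroid"].to_numpy(float),
                   normal_centroid=df["normal_centroid"].to_numpy(float),
                   training_provenance=provenance)


def fit_centroids(matrix: pd.DataFrame, metadata: pd.DataFrame,
                  markers: pd.DataFrame | list | None = None,
                  provenance: str = "training") -> CentroidModel:
    """Per-feature class means over all training samples (true labels).

    Samples a clustering step would misclassify are included — the centroid is
    defined by the recorded class labels, not by any upstream partition.
    """
    if markers is None:
        feats = matrix.index
    else:
        wanted = markers.index if isinstance(markers, pd.DataFrame) else pd.Index(markers)
        feats = wanted.intersection(matrix.index)
    labels = metadata.loc[metadata.index.intersection(matrix.columns), "class_label"]
    tumor_ids = labels.index[labels == "tumor"]
    normal_ids = labels.index[labels == "normal"]
    if len(tumor_ids) == 0 or len(normal_ids) == 0:
        raise ValidationError(
            f"both classes required: {len(tumor_ids)} tumor, {len(normal_ids)} normal")
    sub = matrix.loc[feats]
    if sub.isna().any().any():
        raise ValidationError("centroid training matrix must have no missing values")
    return CentroidModel(
        feature_ids=list(feats.astype(str)),
        tumor_centroid=sub[tumor_ids].mean(axis=1).to_numpy(float),
        normal_centroid=sub[normal_ids].mean(axis=1).to_numpy(float),
        training_provenance=provenance,
    )


def classify_cohort(matrix: pd.DataFrame, model: CentroidModel) -> pd.DataFrame:
    """Correlate each sample with both centroids and predict the closer class.

    Correlations use only features shared between the matrix and the model;
    fewer than 3 shared features is refused (Pearson r has no stability there).
    Zero-variance test profiles get ``predicted = None`` with a diagnostic
    flag instead of a guess.
    """
    shared = pd.Index(model.feature_ids).intersection(matrix.index)
    if len(shared) < MIN_OVERLAP:
        raise ValidationError(
            f"only {len(shared)} overlapping feature(s) between matrix and model; "
            f">= {MIN_OVERLAP} required")
    mframe = model.to_frame().loc[shared]
    tc = mframe["tumor_centroid"].to_numpy(float)
    nc = mframe["normal_centroid"].to_numpy(float)
    X = matrix.loc[shared].to_numpy(float)
    rows = []
    for j, sid in enumerate(matrix.columns):
        x = X[:, j]
        if np.isclose(np.std(x), 0.0):
            rows.append({"sample_id": sid, "r_tumor": np.nan, "r_normal": np.nan,
                         "predicted": None, "n_features_used": len(shared),
                         "flag": "zero_variance_profile"})
            continue
        r_t = float(np.corrcoef(x, tc)[0, 1])
        r_n = float(np.corrcoef(x, nc)[0, 1])
        flag = "tie" if r_t == r_n else ""
        rows.append({"sample_id": sid, "r_tumor": r_t, "r_normal": r_n,
                     "predicted": "tumor" if r_t >= r_n else "normal",
                     "n_features_used": len(shared), "flag": flag})
    return pd.DataFrame(rows).set_index("sample_id")


def evaluate_predictions(predictions: pd.DataFrame, truth: pd.Series | pd.DataFrame
                         ) -> ClassificationReport:
    """Confusion report of centroid predictions against true labels."""
    if len(predictions) == 0:
        raise ValidationError("empty prediction set")
    if isinstance(truth, pd.DataFrame):
        truth = truth["class_label"]
    predicted = predictions["predicted"].dropna()
    return confusion_report(predicted, truth)
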
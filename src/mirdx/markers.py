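"""Differential expression statistics and diagnostic-marker selection.

A feature is retained as a diagnostic marker when three gates pass together:
fold change > 2 or < 0.5 between tumor and normal (geometric-mean ratio,
``2^Δlog2``), two-sided t-test p < 0.05 (classical pooled-variance unpaired t,
or one-sample t on within-pair differences for the paired design), and
permutation-based SAM FDR (q-value) < 0.05.

The SAM relative difference is ``d = (mean₁ − mean₂) / (s + s0)`` with ``s``
the Tusher-style pooled standard error and ``s0`` a fixed percentile of the
per-feature ``s`` distribution.  q-values come from group-label permutations
(sign-flips of pair differences in the paired design): for each feature the
median permutation count of features exceeding its |d| is divided by the
observed count, then monotonized so q never increases with |d|.
Permutations are enumerated exhaustively when the permutation space is small
(≤ 10,000), otherwise sampled with a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class Thresholds:
    """Marker-selection gates."""

    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    fdr: float = 0.05
    sam_s0_percentile: float = 0.05
    n_permutations: int = 1000

    def validate(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValidationError("need 0 < fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1 and 0 < self.fdr < 1):
            raise ValidationError("alpha and fdr must lie in (0, 1)")
        if not (0 <= self.sam_s0_percentile <= 1):
            raise ValidationError("sam_s0_percentile must lie in [0, 1]")


def _split_groups(matrix: pd.DataFrame, groups: pd.Series | dict,
                  design: str, metadata: pd.DataFrame | None = None):
    """Return (tumor_values, normal_values) feature × sample arrays.

    For the paired design the columns of the two arrays are aligned by pair.
    """
    groups = pd.Series(groups)
    groups = groups[groups.index.intersection(matrix.columns)]
    tumor_ids = groups.index[groups == "tumor"].tolist()
    normal_ids = groups.index[groups == "normal"].tolist()
    if design == "unpaired":
        if len(tumor_ids) < 2 or len(normal_ids) < 2:
            raise ValidationError(
                f"each group needs >= 2 samples, got {len(tumor_ids)} tumor / "
                f"{len(normal_ids)} normal")
        return matrix[tumor_ids].to_numpy(float), matrix[normal_ids].to_numpy(float)
    if design == "paired":
        if metadata is None or "pair_id" not in metadata.columns:
            raise ValidationError("paired design requires metadata with pair_id")
        paired = metadata.loc[metadata.index.intersection(groups.index)]
        paired = paired[paired["pair_id"].notna()]
        t_cols, n_cols = [], []
        for pid, grp in paired.groupby("pair_id"):
            t = grp.index[grp["class_label"] == "tumor"]
            n = grp.index[grp["class_label"] == "normal"]
            if len(t) != 1 or len(n) != 1:
                raise ValidationError(f"incomplete pair {pid!r}")
            t_cols.append(t[0])
            n_cols.append(n[0])
        if len(t_cols) < 2:
            raise ValidationError("paired design needs >= 2 complete pairs")
        return matrix[t_cols].to_numpy(float), matrix[n_cols].to_numpy(float)
    raise ValidationError(f"unknown design {design!r}")


def two_group_stats(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    design: Literal["unpaired", "paired"] = "unpaired",
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """t-test and fold-change statistics per feature (tumor vs normal).

    Returns a DataFrame indexed by feature with columns ``mean_log2_diff``,
    ``fold_change`` (linear scale, ``2^mean_log2_diff``), ``t_stat``, ``t_p``
    and ``design``.
    """
    X, Y = _split_groups(matrix, groups, design, metadata)
    if design == "paired":
        diff = X - Y
        mean_diff = diff.mean(axis=1)
        t_stat, t_p = stats.ttest_1samp(diff, 0.0, axis=1)
    else:
        mean_diff = X.mean(axis=1) - Y.mean(axis=1)
        t_stat, t_p = stats.ttest_ind(X, Y, axis=1, equal_var=True)
    out = pd.DataFrame({
        "mean_log2_diff": mean_diff,
        "fold_change": np.power(2.0, mean_diff),
        "t_stat": t_stat,
        "t_p": t_p,
        "design": design,
    }, index=matrix.index)
    # zero-variance features with zero difference: define p = 1 (no evidence)
    out.loc[np.isnan(out["t_p"]) & (out["mean_log2_diff"] == 0.0), "t_p"] = 1.0
    return out


def _sam_d_unpaired(X: np.ndarray, Y: np.ndarray, s0: float | None,
                    s0_percentile: float) -> tuple[np.ndarray, float]:
    n1, n2 = X.shape[1], Y.shape[1]
    r = X.mean(axis=1) - Y.mean(axis=1)
    ss = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    if s0 is None:
        s0 = float(np.percentile(s, 100.0 * s0_percentile))
    return r / (s + s0), s0


def _sam_d_paired(D: np.ndarray, s0: float | None,
                  s0_percentile: float) -> tuple[np.ndarray, float]:
    n = D.shape[1]
    r = D.mean(axis=1)
    s = D.std(axis=1, ddof=1) / np.sqrt(n)
    if s0 is None:
        s0 = float(np.percentile(s, 100.0 * s0_percentile))
    return r / (s + s0), s0


def _q_from_permutations(d_obs: np.ndarray, d_perm: np.ndarray) -> np.ndarray:
    """Per-feature q-values from permuted d matrices.

    ``d_perm`` has shape (B, n_features).  For feature i with threshold
    t = |d_i|: q_raw = median_B #{j: |d*_Bj| >= t} / #{j: |d_j| >= t}, clipped
    to [0, 1], then monotonized (q non-increasing in |d|).
    """
    t = np.abs(d_obs)
    abs_perm_sorted = np.sort(np.abs(d_perm), axis=1)
    n_feat = len(t)
    # counts of permuted |d| >= t_i per permutation, via searchsorted
    fp = n_feat - np.stack([np.searchsorted(row, t, side="left")
                            for row in abs_perm_sorted])
    v = np.median(fp, axis=0)
    obs_sorted = np.sort(t)
    r = n_feat - np.searchsorted(obs_sorted, t, side="left")
    q_raw = np.clip(v / np.maximum(r, 1), 0.0, 1.0)
    # monotonize BH-style: each feature takes the minimum raw estimate over
    # itself and all less significant features, so q never increases with |d|
    order = np.argsort(t, kind="stable")  # least significant first
    q = q_raw.copy()
    q[order] = np.minimum.accumulate(q_raw[order])
    return q


def _unpaired_permutations(n1: int, n2: int, B: int, rng: np.random.Generator):
    """Yield boolean masks (length n1+n2, True = group-1 slot)."""
    n = n1 + n2
    if comb(n, n1) <= EXHAUSTIVE_LIMIT:
        masks = np.zeros((comb(n, n1), n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks
    masks = np.zeros((B, n), dtype=bool)
    for b in range(B):
        masks[b, rng.permutation(n)[:n1]] = True
    return masks


def _paired_signs(n_pairs: int, B: int, rng: np.random.Generator) -> np.ndarray:
    if 2 ** n_pairs <= EXHAUSTIVE_LIMIT:
        grid = np.array(np.meshgrid(*([[1.0, -1.0]] * n_pairs),
                                    indexing="ij")).reshape(n_pairs, -1).T
        return grid
    return rng.choice([1.0, -1.0], size=(B, n_pairs))


def sam_stats(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    design: Literal["unpaired", "paired"] = "unpaired",
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """SAM relative-difference statistics and permutation q-values per feature.

    Deterministic given ``seed``; exhaustive over the permutation space when it
    holds at most 10,000 assignments.
    """
    thresholds.validate()
    if thresholds.n_permutations < 10:
        raise ValidationError("n_permutations must be >= 10")
    if thresholds.n_permutations < 100:
        log.warning("n_permutations = %d is low; q-values will be coarse",
                    thresholds.n_permutations)
    X, Y = _split_groups(matrix, groups, design, metadata)
    rng = np.random.default_rng(seed)
    if design == "paired":
        D = X - Y
        d_obs, s0 = _sam_d_paired(D, None, thresholds.sam_s0_percentile)
        signs = _paired_signs(D.shape[1], thresholds.n_permutations, rng)
        d_perm = np.stack([_sam_d_paired(D * sg[None, :], s0,
                                         thresholds.sam_s0_percentile)[0]
                           for sg in signs])
    else:
        pooled = np.concatenate([X, Y], axis=1)
        n1 = X.shape[1]
        d_obs, s0 = _sam_d_unpaired(X, Y, None, thresholds.sam_s0_percentile)
        masks = _unpaired_permutations(n1, Y.shape[1], thresholds.n_permutations, rng)
        d_perm = np.stack([_sam_d_unpaired(pooled[:, m], pooled[:, ~m], s0,
                                           thresholds.sam_s0_percentile)[0]
                           for m in masks])
    q = _q_from_permutations(d_obs, d_perm)
    return pd.DataFrame({"sam_d": d_obs, "sam_q": q, "sam_s0": s0,
                         "design": design}, index=matrix.index)


def diff_stats(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    design: Literal["unpaired", "paired"] = "unpaired",
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
    sam: bool = True,
) -> pd.DataFrame:
    """Combined t-test + SAM table (the full per-feature statistic set)."""
    tt = two_group_stats(matrix, groups, design, metadata)
    if sam:
        sm = sam_stats(matrix, groups, design, thresholds, seed, metadata)
        tt = tt.join(sm[["sam_d", "sam_q", "sam_s0"]])
    return tt


def select_markers(stats_df: pd.DataFrame, thresholds: Thresholds = Thresholds(),
                   provenance: str = "unpaired_cohort") -> pd.DataFrame:
    """Apply the fold-change / p / FDR gates and record marker directions.

    Returns a DataFrame indexed by feature_id with columns ``direction``
    (up/down from the sign of the mean log2 difference) and ``provenance``.
    The SAM gate is skipped for tables without a ``sam_q`` column (the blood
    analysis uses t-tests only).
    """
    thresholds.validate()
    fc = stats_df["fold_change"]
    keep = ((fc > thresholds.fc_up) | (fc < thresholds.fc_down)) & \
        (stats_df["t_p"] < thresholds.alpha)
    if "sam_q" in stats_df.columns:
        keep &= stats_df["sam_q"] < thresholds.fdr
    sel = stats_df[keep]
    return pd.DataFrame({
        "direction": np.where(sel["mean_log2_diff"] > 0, "up", "down"),
        "provenance": provenance,
    }, index=sel.index.rename("feature_id"))


def union_marker_sets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Union of two marker sets keyed by feature_id.

    Provenance strings are merged (semicolon-joined, sorted); features whose
    directions disagree between the inputs are excluded with a warning.
    """
    merged = a.join(b, how="outer", lsuffix="_a", rsuffix="_b")
    direction = merged["direction_a"].fillna(merged["direction_b"])
    conflict = merged["direction_a"].notna() & merged["direction_b"].notna() & \
        (merged["direction_a"] != merged["direction_b"])
    if conflict.any():
        log.warning("excluding %d marker(s) with conflicting directions: %s",
                    int(conflict.sum()), merged.index[conflict].tolist())
    prov = merged.apply(
        lambda row: ";".join(sorted(
            set(filter(pd.notna, [row.get("provenance_a"), row.get("provenance_b")])))),
        axis=1)
    out = pd.DataFrame({"direction": direction, "provenance": prov},
                       index=merged.index)
    return out[~conflict]


def histology_profile(matrix: pd.DataFrame, metadata: pd.DataFrame,
                      markers: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-(marker, histology) expression comparison against normal tissue.

    Unpaired t-test of each tumor histology subgroup vs the normal samples;
    subgroups with fewer than 2 samples are reported with p = NaN and
    significant = False.  Histologies absent from the cohort are omitted with
    a warning.
    """
    normals = metadata.index[metadata["class_label"] == "normal"]
    normals = normals.intersection(matrix.columns)
    if len(normals) == 0:
        raise ValidationError("no normal samples in cohort")
    feats = markers.index.intersection(matrix.index)
    rows = []
    for hist in ("NSCLC", "SCLC", "carcinoid"):
        members = metadata.index[(metadata["histology"] == hist) &
                                 (metadata["class_label"] == "tumor")]
        members = members.intersection(matrix.columns)
        if len(members) == 0:
            log.warning("histology %s absent from cohort; omitted", hist)
            continue
        sub = matrix.loc[feats, members].to_numpy(float)
        ref = matrix.loc[feats, normals].to_numpy(float)
        diff = sub.mean(axis=1) - ref.mean(axis=1)
        if len(members) >= 2:
            _, p = stats.ttest_ind(sub, ref, axis=1, equal_var=True)
        else:
            p = np.full(len(feats), np.nan)
        for f, d, pv in zip(feats, diff, p):
            rows.append({"feature_id": f, "histology": hist,
                         "mean_log2_diff": d, "p": pv,
                         "significant": bool(pv < alpha) if np.isfinite(pv) else False})
    prof = pd.DataFrame(rows)
    if prof.empty:
        return prof
    consist = (prof.groupby("feature_id")
               .apply(lambda g: bool((g["mean_log2_diff"] > 0).all() and g["significant"].all()),
                      include_groups=False))
    prof["consistently_over_expressed"] = prof["feature_id"].map(consist)
    return prof
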
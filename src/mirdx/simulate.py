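"""Synthetic cohort generators with the statistical structure the pipeline assumes.

Four generators cover the study designs downstream stages consume:

* :func:`gen_expression_cohort` — a two-class log2 expression cohort with
  planted fold-change markers and a matched tumor/normal paired subset.
* :func:`gen_survival` — exponential proportional-hazards event times linked
  to chosen driver features, with independent administrative censoring.
* :func:`gen_pharmaco_panel` — per-drug log-IC50 responses for a cell-line
  panel plus mRNA and protein layers in which designated genes track
  sensitivity or resistance to a named drug.
* :func:`gen_dependency_screen` — gene × line knockout/knockdown effects with
  essential / non-essential anchor genes and per-line affine distortion, so
  anchor-based normalization is non-trivial.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError

#: Baseline log2 abundance around which features are centered.
BASELINE_LOG2 = 8.0


@dataclass(frozen=True)
class SimulationSpec:
    """Design of a two-class expression cohort.

    Defaults mirror the training design the pipeline targets: 87 tumors vs 22
    normals with all 22 normals paired, 4-fold planted markers
    (``planted_log2fc = 2`` log2 units) and unit log2 noise.
    """

    n_features: int = 200
    n_tumor: int = 87
    n_normal: int = 22
    n_paired: int = 22
    n_planted_up: int = 20
    n_planted_down: int = 20
    planted_log2fc: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    #: seed for the per-feature baseline draw; share it between cohorts to
    #: emulate the same biology sampled twice (training vs validation sets)
    baseline_seed: int | None = None

    def validate(self) -> None:
        counts = {
            "n_features": self.n_features, "n_tumor": self.n_tumor,
            "n_normal": self.n_normal, "n_paired": self.n_paired,
            "n_planted_up": self.n_planted_up, "n_planted_down": self.n_planted_down,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.n_planted_up + self.n_planted_down > self.n_features:
            raise ValidationError(
                f"n_planted_up + n_planted_down = "
                f"{self.n_planted_up + self.n_planted_down} exceeds n_features = "
                f"{self.n_features}")
        if self.n_paired > min(self.n_tumor, self.n_normal):
            raise ValidationError(
                f"n_paired = {self.n_paired} exceeds min(n_tumor, n_normal) = "
                f"{min(self.n_tumor, self.n_normal)}")
        if self.planted_log2fc <= 0:
            raise ValidationError("planted_log2fc must be > 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class SyntheticCohort:
    """Expression matrix + metadata + planted-feature truth table."""

    expression: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame  # columns: feature_id (index), direction in {up, down}


def gen_expression_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Simulate a log2 tumor/normal cohort with planted differential markers.

    Planted-up features have tumor mean = normal mean + ``planted_log2fc``;
    planted-down features the negation; all other features share means.  Noise
    is i.i.d. Gaussian on the log2 scale.  Paired samples share a Gaussian
    random intercept (sd = noise_sd / 2), so paired designs gain power the way
    matched-tissue cohorts do.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_tumor + spec.n_normal
    feature_ids = [f"miR-{i:04d}" for i in range(spec.n_features)]
    tumor_ids = [f"T{i:03d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i:03d}" for i in range(spec.n_normal)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([True] * spec.n_tumor + [False] * spec.n_normal)

    base_rng = rng if spec.baseline_seed is None \
        else np.random.default_rng(spec.baseline_seed)
    base = BASELINE_LOG2 + base_rng.normal(0.0, 1.0, size=spec.n_features)
    means = np.tile(base[:, None], (1, n_samples))
    up_idx = np.arange(spec.n_planted_up)
    down_idx = np.arange(spec.n_planted_up, spec.n_planted_up + spec.n_planted_down)
    means[np.ix_(up_idx, np.flatnonzero(is_tumor))] += spec.planted_log2fc
    means[np.ix_(down_idx, np.flatnonzero(is_tumor))] -= spec.planted_log2fc

    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)

    # matched pairs: first n_paired tumors with first n_paired normals share an
    # individual-level intercept
    pair_ids = [None] * n_samples
    for k in range(spec.n_paired):
        intercept = rng.normal(0.0, spec.noise_sd / 2.0)
        t_col, n_col = k, spec.n_tumor + k
        values[:, t_col] += intercept
        values[:, n_col] += intercept
        pair_ids[t_col] = pair_ids[n_col] = f"P{k:03d}"

    expression = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                              columns=sample_ids)
    expression.attrs["layer"] = "miRNA"
    metadata = pd.DataFrame({
        "class_label": np.where(is_tumor, "tumor", "normal"),
        "pair_id": pair_ids,
        "histology": [None] * n_samples,
        "stage": [None] * n_samples,
        "radiotherapy": [None] * n_samples,
        "time_months": [np.nan] * n_samples,
        "event": [None] * n_samples,
    }, index=pd.Index(sample_ids, name="sample_id"))
    # NSCLC for most tumors, a sprinkle of SCLC / carcinoid so histology
    # profiling is exercisable; normals labelled normal
    hist = np.where(is_tumor, "NSCLC", "normal").astype(object)
    n_other = min(4, spec.n_tumor)
    for j in range(n_other):
        hist[spec.n_tumor - 1 - j] = "SCLC" if j % 2 == 0 else "carcinoid"
    metadata["histology"] = hist

    truth = pd.DataFrame({
        "direction": ["up"] * spec.n_planted_up + ["down"] * spec.n_planted_down,
    }, index=pd.Index([feature_ids[i] for i in np.concatenate([up_idx, down_idx])],
                      name="feature_id"))
    return SyntheticCohort(expression=expression, metadata=metadata, truth=truth)


def _censor_horizon(base_rate: float, censor_rate: float) -> float:
    """Administrative horizon τ with E[censored fraction] = censor_rate.

    For T ~ Exp(λ) and C ~ Uniform(0, τ): P(T > C) = (1 − e^{−λτ})/(λτ).
    """
    f = lambda tau: (1.0 - np.exp(-base_rate * tau)) / (base_rate * tau) - censor_rate
    # f decreases from 1 (τ→0) to 0 (τ→∞)
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, lo, hi)


def gen_survival(
    cohort: SyntheticCohort,
    driver_features: Sequence[str],
    log_hr_per_unit: float = 0.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    median_months: float = 30.0,
) -> pd.DataFrame:
    """Attach exponential proportional-hazards survival to a cohort's metadata.

    The linear predictor is ``log_hr_per_unit`` × (mean of the centered driver
    feature values); the baseline hazard gives a median survival of
    ``median_months`` at the covariate mean.  Censoring is independent
    uniform-administrative at the stated expected rate.  Returns augmented
    metadata (times in months, strictly positive).
    """
    if cohort.expression.shape[1] == 0:
        raise ValidationError("empty cohort")
    missing = [f for f in driver_features if f not in cohort.expression.index]
    if missing:
        raise ValidationError(f"driver feature(s) not in cohort: {missing}")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base_rate = np.log(2.0) / median_months
    if driver_features:
        x = cohort.expression.loc[list(driver_features)].to_numpy(dtype=float)
        x = (x - x.mean(axis=1, keepdims=True)).mean(axis=0)
    else:
        x = np.zeros(cohort.expression.shape[1])
    rates = base_rate * np.exp(log_hr_per_unit * x)
    times = rng.exponential(1.0 / rates)
    events = np.ones(len(times), dtype=bool)
    if censor_rate > 0.0:
        tau = _censor_horizon(base_rate, censor_rate)
        censor_times = rng.uniform(0.0, tau, size=len(times))
        events = times <= censor_times
        times = np.minimum(times, censor_times)
    times = np.maximum(times, 1e-6)
    meta = cohort.metadata.copy()
    meta["time_months"] = times
    meta["event"] = events
    return meta


def gen_pharmaco_panel(
    n_lines: int,
    n_drugs: int,
    linked_genes: Mapping[str, tuple[str, str]],
    seed: int = 0,
    n_background: int = 20,
    effect_log2: float = 2.0,
    noise_sd: float = 1.0,
    shared_response_weight: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a drug-response panel with expression-linked sensitivity.

    Returns ``(panel, mrna, protein)``: a long-format response table
    (ln_IC50 per cell line per drug) plus mRNA and protein log2 matrices.  A
    gene linked ``(drug, "sensitive")`` is expressed higher in lines with low
    ln_IC50 for that drug (and mirrored for ``"resistant"``), in both layers.
    The same response-driven signal enters both layers while measurement noise
    is independent per layer, so a linked gene's mRNA–protein correlation is
    ``effect² / (effect² + noise²)`` (0.8 at the defaults) and an unlinked
    gene's layers are uncorrelated.  The protein layer is mean-centered at 0
    per gene.

    Drug responses share a line-level general-sensitivity factor with variance
    fraction ``shared_response_weight`` — cell lines that are broadly sensitive
    tend to be sensitive to every drug, as in real panels.  This is what makes
    "lack of resistance to all drugs" a recoverable signal for a linked gene
    rather than a coin-flip across two-sided tests.
    """
    if n_drugs < 1:
        raise ValidationError("n_drugs must be >= 1")
    if n_lines < 2:
        raise ValidationError("n_lines must be >= 2")
    drugs = [f"drug{j:02d}" for j in range(n_drugs)]
    for gene, (drug, direction) in linked_genes.items():
        if drug not in drugs:
            raise ValidationError(f"linked gene {gene!r} names unknown drug {drug!r}")
        if direction not in ("sensitive", "resistant"):
            raise ValidationError(f"direction must be sensitive|resistant, got {direction!r}")
    rng = np.random.default_rng(seed)
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    # per-drug log-response = shared general-sensitivity factor + drug-specific part
    w = float(np.clip(shared_response_weight, 0.0, 1.0))
    general = rng.normal(0.0, 1.0, size=n_lines)
    specific = rng.normal(0.0, 1.0, size=(n_drugs, n_lines))
    response = np.sqrt(w) * general[None, :] + np.sqrt(1.0 - w) * specific
    panel = pd.DataFrame({
        "cell_line": np.repeat(lines, n_drugs),
        "drug": drugs * n_lines,
        "measure": "ln_IC50",
        "value": response.T.reshape(-1),
        "source": "synthetic",
    })

    genes = list(linked_genes) + [f"GENE{k:03d}" for k in range(n_background)]
    mrna = np.empty((len(genes), n_lines))
    prot = np.empty((len(genes), n_lines))
    for gi, gene in enumerate(genes):
        if gene in linked_genes:
            drug, direction = linked_genes[gene]
            z = response[drugs.index(drug)]
            z = (z - z.mean()) / z.std()
            signal = (-z if direction == "sensitive" else z) * effect_log2
        else:
            signal = np.zeros(n_lines)
        mrna[gi] = BASELINE_LOG2 + signal + rng.normal(0, noise_sd, n_lines)
        prot[gi] = signal + rng.normal(0, noise_sd, n_lines)
    mrna_df = pd.DataFrame(mrna, index=pd.Index(genes, name="feature_id"), columns=lines)
    prot_df = pd.DataFrame(prot, index=pd.Index(genes, name="feature_id"), columns=lines)
    prot_df = prot_df.sub(prot_df.mean(axis=1), axis=0)  # protein layer centered at 0
    mrna_df.attrs["layer"] = "mRNA"
    prot_df.attrs["layer"] = "protein"
    return panel, mrna_df, prot_df


@dataclass
class DependencyScreen:
    """Gene × cell-line knockout/knockdown effect matrix with anchor gene sets."""

    assay: str  # "CRISPR" or "RNAi"
    raw: pd.DataFrame
    essential_ids: list[str]
    nonessential_ids: list[str]
    normalized: pd.DataFrame | None = None


def gen_dependency_screen(
    n_genes: int,
    n_lines: int,
    essential_ids: Sequence[str],
    nonessential_ids: Sequence[str],
    dependent_ids: Mapping[str, float] | None = None,
    seed: int = 0,
    assay: str = "CRISPR",
    anchor_sd: float = 0.1,
    effect_mean: float = -0.9,
) -> DependencyScreen:
    """Simulate a dependency screen with per-line affine distortion.

    On the latent (normalized) scale, essential anchors are centered at −1 and
    non-essential anchors at 0; genes in ``dependent_ids`` score below −0.5 in
    the stated fraction of lines.  Each line then receives a random gain and
    offset so that anchor-based normalization is non-trivial.
    """
    essential_ids = list(essential_ids)
    nonessential_ids = list(nonessential_ids)
    overlap = set(essential_ids) & set(nonessential_ids)
    if overlap:
        raise ValidationError(f"essential/non-essential sets overlap: {sorted(overlap)}")
    dependent_ids = dict(dependent_ids or {})
    rng = np.random.default_rng(seed)
    lines = [f"CL{i:03d}" for i in range(n_lines)]
    named = essential_ids + nonessential_ids + [g for g in dependent_ids
                                                if g not in essential_ids + nonessential_ids]
    fillers = [f"DEP{k:03d}" for k in range(max(0, n_genes - len(named)))]
    genes = named + fillers

    latent = np.empty((len(genes), n_lines))
    for gi, gene in enumerate(genes):
        if gene in essential_ids:
            latent[gi] = rng.normal(-1.0, anchor_sd, n_lines)
        elif gene in nonessential_ids:
            latent[gi] = rng.normal(0.0, anchor_sd, n_lines)
        elif gene in dependent_ids:
            frac = float(dependent_ids[gene])
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"fraction_affected for {gene!r} must be in [0,1]")
            n_hit = int(round(frac * n_lines))
            hit = rng.permutation(n_lines)[:n_hit]
            row = rng.normal(0.0, anchor_sd, n_lines)
            row[hit] = rng.normal(effect_mean, anchor_sd, n_hit)
            latent[gi] = row
        else:
            latent[gi] = rng.normal(0.0, 0.15, n_lines)

    gain = rng.uniform(0.5, 2.0, size=n_lines)
    offset = rng.uniform(-0.5, 0.5, size=n_lines)
    raw = latent * gain[None, :] + offset[None, :]
    raw_df = pd.DataFrame(raw, index=pd.Index(genes, name="gene_id"), columns=lines)
    return DependencyScreen(assay=assay, raw=raw_df,
                            essential_ids=essential_ids,
                            nonessential_ids=nonessential_ids)
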
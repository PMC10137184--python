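"""Survival machinery: Kaplan–Meier, log-rank, univariate Cox, optimal-cutoff
dichotomization, and the oncogene/suppressor and prognostic-gene rules.

The optimal-cutoff procedure scans candidate log2-expression thresholds
(unique observed values keeping both groups at >= 10% of the cohort), runs a
log-rank test at each, and keeps the split with the smallest p-value.  No
multiplicity correction is applied — the scan is anti-conservative by
construction, which is surfaced in the returned summary rather than hidden.

Categorization rules:

* a miRNA over-expressed in tumors with hazard ratio > 1 (p < 0.05) in every
  required cohort is called *oncogenic*; under-expressed with HR < 1
  everywhere significant is *suppressive*; anything else is *neither*.
* a gene is *hazardous* (*protective*) when at least two of five evidence
  categories point that way and none points the other way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as sp_stats

from .errors import ValidationError

REQUIRED_COHORTS = ("LUAD", "LUSC", "combined")


@dataclass
class SurvivalCurve:
    """Product-limit estimate: right-continuous step function starting at 1."""

    times: np.ndarray
    survival: np.ndarray

    def probability(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def __call__(self, t: float) -> float:
        return self.probability(t)


@dataclass
class SurvivalSummary:
    feature_id: str
    cohort_id: str
    cutoff: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    min_p_scan: bool = True  # cutoff chosen by minimum p: anti-conservative


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValidationError("empty survival input")
    if (times < 0).any():
        raise ValidationError("times must be >= 0")
    return times, events


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return SurvivalCurve(times=sf.index.to_numpy(float),
                         survival=sf.iloc[:, 0].to_numpy(float))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) at 1 df.

    Standard observed-minus-expected statistic with the hypergeometric
    variance, computed directly from the risk tables (kept in-package because
    the optimal-cutoff scan evaluates it at every candidate threshold).
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dead = events & (times == t)
        d = int(dead.sum())
        d1 = int((dead & in_a).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(sp_stats.chi2.sf(chi2, df=1))


def cox_binary(times_a, events_a, times_b, events_b
               ) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox fit on a binary covariate (group A = 1, B = 0).

    Returns (hazard ratio for A vs B, Wald 95% CI, Wald p).  Ties are handled
    by the Breslow approximation.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if not ea.any() and not eb.any():
        raise ValidationError("no events in either group: HR unidentifiable")
    df = pd.DataFrame({
        "time": np.concatenate([ta, tb]),
        "event": np.concatenate([ea, eb]).astype(int),
        "group": np.concatenate([np.ones(len(ta)), np.zeros(len(tb))]),
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    p = float(cph.summary.loc["group", "p"])
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return float(np.exp(beta)), ci, p


def optimal_cutoff(expression: pd.Series, times, events,
                   min_group_fraction: float = 0.10,
                   cohort_id: str = "", feature_id: str = "") -> SurvivalSummary:
    """Smallest-log-rank-p expression cutoff dichotomizing a cohort.

    Candidates are unique observed values where both sides (high = value >
    cutoff) hold at least ``min_group_fraction`` of the cohort.  The hazard
    ratio at the chosen cutoff comes from a univariate Cox fit (high vs low).
    """
    expression = pd.Series(expression).astype(float)
    times, events = _check_surv(times, events)
    n = len(expression)
    if n < 20:
        raise ValidationError(f"optimal_cutoff needs >= 20 subjects, got {n}")
    if len(times) != n:
        raise ValidationError("expression and survival lengths differ")
    values = expression.to_numpy()
    min_count = int(np.ceil(min_group_fraction * n))
    candidates = [c for c in np.unique(values)
                  if min_count <= int((values > c).sum()) <= n - min_count]
    if not candidates:
        raise ValidationError("no admissible cutoff (constant or near-constant expression)")
    best = None
    for c in candidates:
        high = values > c
        chi2, p = logrank(times[high], events[high], times[~high], events[~high])
        if best is None or p < best[1]:
            best = (c, p, chi2)
    c, p, chi2 = best
    high = values > c
    hr, ci, _ = cox_binary(times[high], events[high], times[~high], events[~high])
    return SurvivalSummary(feature_id=feature_id, cohort_id=cohort_id,
                           cutoff=float(c), n_high=int(high.sum()),
                           n_low=int((~high).sum()), logrank_chi2=chi2,
                           logrank_p=p, hr=hr, hr_ci=ci)


@dataclass
class MiRNACategory:
    mirna_id: str
    category: str  # oncogenic | suppressive | neither
    evidence: dict = field(default_factory=dict)
    flag: str = ""


def categorize_mirna(
    mirna_id: str,
    evidence: dict,
    tumor_direction: str,
    required_cohorts=REQUIRED_COHORTS,
    alpha: float = 0.05,
    concordance: str = "all",
) -> MiRNACategory:
    """Oncogene/suppressor call from per-cohort (hr, p) evidence.

    ``evidence`` maps cohort id → (hr, p).  Oncogenic requires hr > 1 with
    p < alpha in the required cohorts and over-expression in tumors;
    suppressive is the mirror.  ``concordance='all'`` requires every cohort,
    ``'majority'`` more than half.  Missing cohorts yield ``neither`` with an
    "insufficient evidence" flag under the all-required policy.
    """
    if tumor_direction not in ("up", "down"):
        raise ValidationError("tumor_direction must be 'up' or 'down'")
    present = [c for c in required_cohorts if c in evidence]
    missing = [c for c in required_cohorts if c not in evidence]
    if concordance == "all" and missing:
        return MiRNACategory(mirna_id, "neither", dict(evidence),
                             flag=f"insufficient evidence: missing {missing}")
    need = len(required_cohorts) if concordance == "all" \
        else len(required_cohorts) // 2 + 1
    n_onc = sum(1 for c in present
                if evidence[c][0] > 1 and evidence[c][1] < alpha)
    n_sup = sum(1 for c in present
                if evidence[c][0] < 1 and evidence[c][1] < alpha)
    if tumor_direction == "up" and n_onc >= need:
        return MiRNACategory(mirna_id, "oncogenic", dict(evidence))
    if tumor_direction == "down" and n_sup >= need:
        return MiRNACategory(mirna_id, "suppressive", dict(evidence))
    return MiRNACategory(mirna_id, "neither", dict(evidence))


@dataclass
class PrognosticGeneCall:
    gene_id: str
    category: str  # hazardous | protective | neither
    n_supporting: int


def prognostic_gene_call(gene_id: str, evidence) -> PrognosticGeneCall:
    """Two-of-five concordance rule with a contradiction veto.

    ``evidence`` is an iterable of up to five entries in
    {"hazardous", "protective", None}.  A non-neither call needs >= 2
    supporting entries and zero contradicting ones.
    """
    evidence = list(evidence)
    if len(evidence) > 5:
        raise ValidationError("at most 5 evidence categories")
    bad = [e for e in evidence if e not in ("hazardous", "protective", None)]
    if bad:
        raise ValidationError(f"unknown evidence value(s): {bad}")
    n_h = evidence.count("hazardous")
    n_p = evidence.count("protective")
    if n_h >= 2 and n_p == 0:
        return PrognosticGeneCall(gene_id, "hazardous", n_h)
    if n_p >= 2 and n_h == 0:
        return PrognosticGeneCall(gene_id, "protective", n_p)
    return PrognosticGeneCall(gene_id, "neither", max(n_h, n_p))
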
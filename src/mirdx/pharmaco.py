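"""Drug-response, radiotherapy and dependency-screen calling.

Cell lines are categorized per (drug, source, measure) by a tertile split of
the response values (lower third = sensitive, upper third = resistant, middle
excluded); the split is deterministic and scale-free.  A feature is called
*sensitive* to a drug when its expression is significantly higher (two-sample
t-test, p < 0.05) in the sensitive lines, *resistant* when higher in the
resistant lines, neutral otherwise.  A feature is *pansensitive* across a drug
panel when no drug yields a resistant call in any required layer and at least
one drug yields a sensitive call concordantly in every required layer
(mirrored for *panresistant*); genes require the mRNA and protein layers,
miRNAs the miRNA layer alone.

Dependency screens are renormalized per line by the affine map that sends the
line's essential-anchor median to −1 and its non-essential-anchor median to 0;
a normalized score strictly below −0.5 counts as a significant knockout /
knockdown effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .simulate import DependencyScreen

log = logging.getLogger(__name__)

MIN_LINES_PER_DRUG = 6
SIGNIFICANT_DEPENDENCE = -0.5


def categorize_lines(panel: pd.DataFrame, method: str = "tertile") -> pd.DataFrame:
    """Assign sensitive / resistant / excluded per (cell_line, drug, source, measure).

    Tertile method: per (drug, source, measure), sort lines by response value
    (lower = more sensitive for IC50/EC50-type measures); the lowest
    ``floor(n/3)`` lines are sensitive, the highest ``floor(n/3)`` resistant,
    the middle excluded.  Groups with fewer than 6 lines, or with no ordering
    information (all values tied), are excluded entirely.
    """
    if method != "tertile":
        raise ValidationError(f"unknown categorization method {method!r}")
    out = panel.reset_index(drop=True)  # label assignment needs a unique index
    out["category"] = "excluded"
    for (drug, source, measure), grp in out.groupby(["drug", "source", "measure"]):
        n = len(grp)
        if n < MIN_LINES_PER_DRUG:
            log.warning("drug %s (%s, %s): only %d line(s); all excluded",
                        drug, source, measure, n)
            continue
        if grp["value"].nunique() == 1:
            continue
        k = n // 3
        order = grp["value"].sort_values(kind="stable")
        out.loc[order.index[:k], "category"] = "sensitive"
        out.loc[order.index[-k:], "category"] = "resistant"
    return out


def gene_drug_call(expr: pd.DataFrame, categorized: pd.DataFrame, drug: str,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature sensitive/resistant/neutral call for one drug.

    Combines all (source, measure) categorizations for the drug: a feature is
    sensitive (resistant) if any source-measure yields that significant
    direction; conflicting directions across sources veto to neutral.
    """
    sub = categorized[categorized["drug"] == drug]
    if sub.empty:
        raise ValidationError(f"drug {drug!r} not in panel")
    per_sm = []
    for (source, measure), grp in sub.groupby(["source", "measure"]):
        sens = [l for l in grp.loc[grp["category"] == "sensitive", "cell_line"]
                if l in expr.columns]
        res = [l for l in grp.loc[grp["category"] == "resistant", "cell_line"]
               if l in expr.columns]
        if len(sens) < 2 or len(res) < 2:
            per_sm.append(pd.DataFrame({
                "call": "neutral", "p": np.nan, "flag": "insufficient_lines"},
                index=expr.index))
            continue
        S = expr[sens].to_numpy(float)
        R = expr[res].to_numpy(float)
        t, p = stats.ttest_ind(S, R, axis=1, equal_var=True)
        call = np.where((p < alpha) & (t > 0), "sensitive",
                        np.where((p < alpha) & (t < 0), "resistant", "neutral"))
        per_sm.append(pd.DataFrame({"call": call, "p": p, "flag": ""},
                                   index=expr.index))
    stacked = pd.concat(per_sm, axis=1)
    calls = stacked[["call"]] if len(per_sm) == 1 else stacked["call"]
    flags = stacked[["flag"]] if len(per_sm) == 1 else stacked["flag"]
    any_sens = (calls == "sensitive").any(axis=1)
    any_res = (calls == "resistant").any(axis=1)
    final = np.where(any_sens & ~any_res, "sensitive",
                     np.where(any_res & ~any_sens, "resistant", "neutral"))
    all_insufficient = (flags == "insufficient_lines").all(axis=1)
    flag = np.where(any_sens & any_res, "source_conflict",
                    np.where(all_insufficient, "insufficient_lines", ""))
    pmat = stacked[["p"]] if len(per_sm) == 1 else stacked["p"]
    return pd.DataFrame({"drug": drug, "call": final,
                         "p": pmat.min(axis=1), "flag": flag}, index=expr.index)


@dataclass
class PanCall:
    id: str
    call: str  # pansensitive | panresistant | neither
    n_drugs_evaluated: int
    layers_concordant: bool
    flag: str = ""


def _pan_one_layer(calls: Mapping[str, str]) -> str:
    values = list(calls.values())
    n_sens = values.count("sensitive")
    n_res = values.count("resistant")
    if n_res == 0 and n_sens >= 1:
        return "pansensitive"
    if n_sens == 0 and n_res >= 1:
        return "panresistant"
    return "neither"


def pan_call(feature_id: str, calls_by_layer: Mapping[str, Mapping[str, str]],
             required_layers: Sequence[str]) -> PanCall:
    """Pan-sensitivity call across a drug panel, concordant over layers.

    ``calls_by_layer`` maps layer → {drug → call}.  The feature is
    pansensitive when no drug is called resistant in *any* required layer and
    at least one drug is called sensitive in *every* required layer
    (panresistant is the mirror).  With a single required layer this reduces
    to: no resistant call and at least one sensitive call.  Requiring the
    supporting drug to be concordant across layers keeps a single-layer type-I
    error from manufacturing a pan call.
    """
    missing = [ly for ly in required_layers if ly not in calls_by_layer
               or not calls_by_layer[ly]]
    n_drugs = max((len(calls_by_layer.get(ly, {})) for ly in required_layers),
                  default=0)
    if missing:
        return PanCall(feature_id, "neither", n_drugs, False,
                       flag=f"missing layer(s): {missing}")
    per_layer = {ly: _pan_one_layer(calls_by_layer[ly]) for ly in required_layers}
    concordant = len(set(per_layer.values())) == 1
    layer_calls = [calls_by_layer[ly] for ly in required_layers]
    no_res = all(c != "resistant" for calls in layer_calls for c in calls.values())
    no_sens = all(c != "sensitive" for calls in layer_calls for c in calls.values())
    sens_everywhere = set.intersection(*[
        {d for d, c in calls.items() if c == "sensitive"} for calls in layer_calls])
    res_everywhere = set.intersection(*[
        {d for d, c in calls.items() if c == "resistant"} for calls in layer_calls])
    if no_res and sens_everywhere:
        return PanCall(feature_id, "pansensitive", n_drugs, concordant)
    if no_sens and res_everywhere:
        return PanCall(feature_id, "panresistant", n_drugs, concordant)
    return PanCall(feature_id, "neither", n_drugs, concordant)


def radiotherapy_call(expr: pd.DataFrame, metadata: pd.DataFrame,
                      long_months: float = 58.0, short_months: float = 20.0,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Radiotherapy-response association of each gene.

    Patients are restricted to stage III/IV who received radiotherapy; the
    long-survival group is time > ``long_months`` and the short-survival group
    time < ``short_months`` (open intervals — patients in between are
    excluded).  Genes significantly higher in the long group are
    ``rt_sensitive``; higher in the short group, ``rt_resistant``.
    """
    rt = metadata[(metadata["stage"].isin(["III", "IV"])) &
                  (metadata["radiotherapy"] == True) &  # noqa: E712 (nullable col)
                  metadata["time_months"].notna()]
    long_ids = rt.index[rt["time_months"] > long_months].intersection(expr.columns)
    short_ids = rt.index[rt["time_months"] < short_months].intersection(expr.columns)
    if len(long_ids) < 2 or len(short_ids) < 2:
        raise ValidationError(
            f"need >= 2 patients per survival group, got {len(long_ids)} long / "
            f"{len(short_ids)} short")
    L = expr[long_ids].to_numpy(float)
    S = expr[short_ids].to_numpy(float)
    t, p = stats.ttest_ind(L, S, axis=1, equal_var=True)
    call = np.where((p < alpha) & (t > 0), "rt_sensitive",
                    np.where((p < alpha) & (t < 0), "rt_resistant", "neutral"))
    return pd.DataFrame({"call": call, "p": p,
                         "n_long": len(long_ids), "n_short": len(short_ids)},
                        index=expr.index)


def normalize_dependency(screen: DependencyScreen) -> DependencyScreen:
    """Per-line affine renormalization anchored on essential/non-essential medians.

    For each line with essential-anchor median ``m_ess`` and non-essential
    median ``m_non``, every raw score x maps to ``(x − m_non)/(m_non − m_ess)``
    — the unique affine map sending the anchors to −1 and 0.
    """
    ess = [g for g in screen.essential_ids if g in screen.raw.index]
    non = [g for g in screen.nonessential_ids if g in screen.raw.index]
    if not ess or not non:
        raise ValidationError("both anchor sets must be non-empty and present")
    if set(ess) & set(non):
        raise ValidationError("anchor sets overlap")
    m_ess = screen.raw.loc[ess].median(axis=0)
    m_non = screen.raw.loc[non].median(axis=0)
    degenerate = m_ess.index[np.isclose(m_ess, m_non)]
    if len(degenerate):
        raise ValidationError(
            f"anchor medians coincide in line(s): {degenerate.tolist()}")
    normalized = screen.raw.sub(m_non, axis=1).div(m_non - m_ess, axis=1)
    screen.normalized = normalized
    return screen


@dataclass
class ProliferationProfile:
    gene_id: str
    fraction_significant: dict  # assay -> fraction of lines with score < -0.5
    profile_class: str  # both_major | either_major | none_significant | other
    flag: str = ""


def proliferation_profile(screens: Sequence[DependencyScreen],
                          genes: Iterable[str] | None = None
                          ) -> dict[str, ProliferationProfile]:
    """Per-gene fraction of lines with a significant dependence, per assay.

    ``both_major``: > 50% of lines affected in every assay; ``either_major``:
    in at least one; ``none_significant``: zero affected lines in every assay;
    ``other``: anything else.  Genes missing from an assay are profiled on the
    available assays and flagged.
    """
    for screen in screens:
        if screen.normalized is None:
            raise ValidationError(f"{screen.assay} screen not normalized yet")
    if genes is None:
        genes = sorted(set().union(*[set(s.normalized.index) for s in screens]))
    out = {}
    for gene in genes:
        fractions = {}
        for screen in screens:
            if gene in screen.normalized.index:
                row = screen.normalized.loc[gene].to_numpy(float)
                fractions[screen.assay] = float((row < SIGNIFICANT_DEPENDENCE).mean())
        if not fractions:
            continue
        flag = "" if len(fractions) == len(screens) else "missing_assay"
        fr = list(fractions.values())
        if all(f > 0.5 for f in fr):
            cls = "both_major"
        elif any(f > 0.5 for f in fr):
            cls = "either_major"
        elif all(f == 0.0 for f in fr):
            cls = "none_significant"
        else:
            cls = "other"
        out[gene] = ProliferationProfile(gene, fractions, cls, flag)
    return out


def responder_genes(mrna: pd.DataFrame, protein: pd.DataFrame,
                    categorized: pd.DataFrame, compound: str,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Genes with concordant significant mRNA and protein response association.

    Retains genes significant (p < alpha) in the same direction in both
    layers for the compound; the direction labels the gene
    sensitive-associated or resistant-associated.
    """
    m = gene_drug_call(mrna, categorized, compound, alpha)
    p = gene_drug_call(protein, categorized, compound, alpha)
    shared = m.index.intersection(p.index)
    m, p = m.loc[shared], p.loc[shared]
    keep = (m["call"] == p["call"]) & (m["call"] != "neutral")
    return pd.DataFrame({
        "compound": compound,
        "direction": m.loc[keep, "call"],
        "p_mrna": m.loc[keep, "p"],
        "p_protein": p.loc[keep, "p"],
    }, index=shared[keep])
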
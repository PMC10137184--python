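"""End-to-end orchestration of the marker-discovery and translational stages.

``run_all`` wires the stages in study order on synthetic cohorts:

    simulate → markers → cluster → classify → survival → pharmaco →
    dependency → signature

Each stage writes its outputs under the run directory and feeds the next
stage.  All randomness flows from one top-level seed through per-stage derived
seeds (stable SHA-256 hashing), so every stage is independently reproducible
and two runs with the same config and seed produce byte-identical bundles.
A ``MANIFEST.json`` records the tool version, the config hash and the seed for
the whole bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import matrix_io
from .centroid import classify_cohort, evaluate_predictions, fit_centroids
from .cluster import evaluate_clusters, hcluster_two
from .errors import MirdxError, ValidationError
from .markers import Thresholds, diff_stats, select_markers, union_marker_sets
from .pharmaco import (categorize_lines, gene_drug_call, normalize_dependency,
                       pan_call, proliferation_profile)
from .markers import two_group_stats
from .signatures import build_cmap_lists
from .simulate import (SimulationSpec, SyntheticCohort, gen_dependency_screen,
                       gen_expression_cohort, gen_pharmaco_panel, gen_survival)
from .survival import categorize_mirna, optimal_cutoff, prognostic_gene_call

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Knobs for a full synthetic run; defaults are the study-shaped conditions."""

    seed: int = 0
    cohort: SimulationSpec = field(default_factory=SimulationSpec)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_drugs: int = 21
    n_cell_lines: int = 94
    n_screen_lines: int = 50
    survival_n: int = 200
    log_hr_per_unit: float = 0.6
    censor_rate: float = 0.3
    concordance: str = "all"

    def config_hash(self) -> str:
        payload = json.dumps({"cohort": asdict(self.cohort),
                              "thresholds": asdict(self.thresholds),
                              "n_drugs": self.n_drugs,
                              "n_cell_lines": self.n_cell_lines,
                              "n_screen_lines": self.n_screen_lines,
                              "survival_n": self.survival_n,
                              "log_hr_per_unit": self.log_hr_per_unit,
                              "censor_rate": self.censor_rate,
                              "concordance": self.concordance},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def stage_markers(cohort: SyntheticCohort, thresholds: Thresholds, seed: int
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Unpaired whole-cohort and paired-subset marker selection, then union."""
    groups = cohort.metadata["class_label"]
    stats_unpaired = diff_stats(cohort.expression, groups, "unpaired",
                                thresholds, derive_seed(seed, "sam_unpaired"))
    markers_unpaired = select_markers(stats_unpaired, thresholds, "unpaired_cohort")
    paired_meta = cohort.metadata[cohort.metadata["pair_id"].notna()]
    stats_paired = diff_stats(cohort.expression[paired_meta.index], groups,
                              "paired", thresholds,
                              derive_seed(seed, "sam_paired"), paired_meta)
    markers_paired = select_markers(stats_paired, thresholds, "paired_cohort")
    markers = union_marker_sets(markers_unpaired, markers_paired)
    return stats_unpaired, stats_paired, markers


def _prognostic_gene_universe(rng_seed: int):
    """Planted gene roles for the translational stages.

    Hazardous genes are over-expressed in tumors and raise the hazard;
    protective genes mirror that.  Dependence fractions are planted so each
    signature-list rule has members.
    """
    hazardous = [f"HAZ{i:02d}" for i in range(6)]
    protective = [f"PRO{i:02d}" for i in range(6)]
    background = [f"BGD{i:02d}" for i in range(8)]
    # per-gene (crispr_fraction, rnai_fraction) of affected lines
    dep_fractions = {}
    for i, g in enumerate(hazardous):
        dep_fractions[g] = (0.8, 0.8) if i < 3 else (0.8, 0.2)  # both vs either major
    for g in protective:
        dep_fractions[g] = (0.0, 0.0)
    for g in background:
        dep_fractions[g] = (0.0, 0.0)
    return hazardous, protective, background, dep_fractions


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the aggregated summary (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": config.config_hash(), "stages": {}}
    try:
        # --- simulate + markers + cluster + classify (miRNA diagnostic arm) ---
        baseline_seed = derive_seed(config.seed, "baseline")
        spec = SimulationSpec(**{**asdict(config.cohort),
                                 "seed": derive_seed(config.seed, "cohort"),
                                 "baseline_seed": baseline_seed})
        cohort = gen_expression_cohort(spec)
        matrix_io.write_expression(cohort.expression, out / "expression.tsv")
        matrix_io.write_metadata(cohort.metadata, out / "metadata.tsv")
        cohort.truth.to_csv(out / "truth.tsv", sep="\t")

        stats_u, stats_p, markers = stage_markers(cohort, config.thresholds,
                                                  config.seed)
        stats_u.to_csv(out / "diffstats_unpaired.tsv", sep="\t", float_format="%.6g")
        stats_p.to_csv(out / "diffstats_paired.tsv", sep="\t", float_format="%.6g")
        markers.to_csv(out / "markers.tsv", sep="\t")
        planted = set(cohort.truth.index)
        recovered = set(markers.index) & planted
        summary["stages"]["markers"] = {
            "n_unpaired": int(len(select_markers(stats_u, config.thresholds))),
            "n_paired": int(len(select_markers(stats_p, config.thresholds))),
            "n_union": int(len(markers)),
            "planted_sensitivity": len(recovered) / max(len(planted), 1),
            "false_discoveries": int(len(set(markers.index) - planted)),
        }

        assignment = hcluster_two(cohort.expression, markers)
        report = evaluate_clusters(assignment, cohort.metadata)
        assignment.clusters.to_csv(out / "clusters.tsv", sep="\t")
        _write_json(report.as_dict(), out / "cluster_report.json")
        summary["stages"]["cluster"] = report.as_dict()

        # validation cohort from the same design, new seed (platform shift is
        # emulated by an intersected feature subset)
        val_spec = SimulationSpec(**{**asdict(config.cohort),
                                     "seed": derive_seed(config.seed, "validation"),
                                     "baseline_seed": baseline_seed})
        val = gen_expression_cohort(val_spec)
        keep = sorted(set(markers.index))[: max(3, int(0.65 * len(markers)))]
        model = fit_centroids(cohort.expression, cohort.metadata, markers)
        preds = classify_cohort(val.expression.loc[val.expression.index.isin(
            set(keep) | (set(val.expression.index) - set(markers.index)))], model)
        pred_report = evaluate_predictions(preds, val.metadata)
        preds.to_csv(out / "centroid_predictions.tsv", sep="\t", float_format="%.6g")
        _write_json(pred_report.as_dict(), out / "centroid_report.json")
        summary["stages"]["classify"] = {
            **pred_report.as_dict(),
            "n_features_used": int(preds["n_features_used"].iloc[0]),
        }

        # --- survival: per-cohort optimal-cutoff summaries for the planted driver ---
        driver = cohort.truth.index[0]  # planted-up feature: oncogenic pattern
        suppressor = cohort.truth.index[cohort.truth["direction"] == "down"][0] \
            if (cohort.truth["direction"] == "down").any() else None
        surv_rows = []
        mirna_evidence: dict[str, dict] = {driver: {}}
        if suppressor:
            mirna_evidence[suppressor] = {}
        for cid in ("LUAD", "LUSC", "combined"):
            s_spec = SimulationSpec(
                n_features=spec.n_features,
                n_tumor=config.survival_n, n_normal=0, n_paired=0,
                n_planted_up=spec.n_planted_up, n_planted_down=spec.n_planted_down,
                planted_log2fc=spec.planted_log2fc, noise_sd=spec.noise_sd,
                seed=derive_seed(config.seed, f"surv_{cid}"))
            s_cohort = gen_expression_cohort(s_spec)
            meta = gen_survival(s_cohort, [driver], config.log_hr_per_unit,
                                config.censor_rate,
                                derive_seed(config.seed, f"survtimes_{cid}"))
            if suppressor:
                # suppressor drives survival the other way in the same cohort:
                # regenerate times with a negative coefficient on it as well
                meta2 = gen_survival(s_cohort, [suppressor],
                                     -config.log_hr_per_unit, config.censor_rate,
                                     derive_seed(config.seed, f"survtimes2_{cid}"))
            for fid, m in [(driver, meta)] + ([(suppressor, meta2)] if suppressor else []):
                s = optimal_cutoff(s_cohort.expression.loc[fid],
                                   m["time_months"], m["event"].astype(bool),
                                   cohort_id=cid, feature_id=fid)
                surv_rows.append({"feature_id": fid, "cohort_id": cid,
                                  "cutoff": s.cutoff, "n_high": s.n_high,
                                  "n_low": s.n_low, "chi2": s.logrank_chi2,
                                  "p": s.logrank_p, "hr": s.hr,
                                  "hr_lo": s.hr_ci[0], "hr_hi": s.hr_ci[1]})
                mirna_evidence[fid][cid] = (s.hr, s.logrank_p)
        surv_df = pd.DataFrame(surv_rows)
        surv_df.to_csv(out / "survival_summaries.tsv", sep="\t", index=False,
                       float_format="%.6g")
        categories = {}
        for fid, ev in mirna_evidence.items():
            direction = cohort.truth.loc[fid, "direction"]
            cat = categorize_mirna(fid, ev, direction,
                                   concordance=config.concordance)
            categories[fid] = cat.category
        _write_json(categories, out / "mirna_categories.json")
        summary["stages"]["survival"] = {"categories": categories,
                                         "n_summaries": len(surv_rows)}

        # --- pharmaco: planted pansensitive / panresistant genes ---
        linked = {"SENSG": ("drug00", "sensitive"),
                  "RESG": ("drug01", "resistant")}
        panel, mrna, protein = gen_pharmaco_panel(
            config.n_cell_lines, config.n_drugs, linked,
            seed=derive_seed(config.seed, "pharmaco"))
        categorized = categorize_lines(panel)
        matrix_io.write_drug_panel(categorized, out / "drug_panel.tsv")
        drugs = sorted(categorized["drug"].unique())
        calls_by_layer = {"mRNA": {}, "protein": {}}
        for layer, expr in (("mRNA", mrna), ("protein", protein)):
            per_drug = {d: gene_drug_call(expr, categorized, d) for d in drugs}
            for g in expr.index:
                calls_by_layer[layer][g] = {d: per_drug[d].loc[g, "call"]
                                            for d in drugs}
        pan = {g: pan_call(g, {ly: calls_by_layer[ly][g] for ly in calls_by_layer},
                           ["mRNA", "protein"]).call
               for g in mrna.index}
        _write_json(pan, out / "pan_calls.json")
        summary["stages"]["pharmaco"] = {
            "pansensitive": sorted(g for g, c in pan.items() if c == "pansensitive"),
            "panresistant": sorted(g for g, c in pan.items() if c == "panresistant"),
            "n_drugs": len(drugs),
        }

        # --- dependency + prognostic genes + signature lists ---
        hazardous, protective, background, dep_fr = _prognostic_gene_universe(
            config.seed)
        genes = hazardous + protective + background
        essential = [f"ESS{i:02d}" for i in range(10)]
        nonessential = [f"NON{i:02d}" for i in range(10)]
        screens = []
        for assay, fr_idx in (("CRISPR", 0), ("RNAi", 1)):
            screen = gen_dependency_screen(
                n_genes=len(genes) + 20, n_lines=config.n_screen_lines,
                essential_ids=essential, nonessential_ids=nonessential,
                dependent_ids={g: dep_fr[g][fr_idx] for g in genes},
                seed=derive_seed(config.seed, f"dep_{assay}"), assay=assay)
            screens.append(normalize_dependency(screen))
        profiles = proliferation_profile(screens, genes)
        pd.DataFrame([{"gene_id": g, **p.fraction_significant,
                       "class": p.profile_class}
                      for g, p in profiles.items()]).to_csv(
            out / "proliferation_profiles.tsv", sep="\t", index=False,
            float_format="%.6g")

        # gene-level prognostic evidence: tumor/normal mRNA cohort + two
        # survival cohorts per gene direction
        prog_seed = derive_seed(config.seed, "prognostic")
        gene_cohort = _gene_expression_cohort(hazardous, protective, background,
                                              prog_seed)
        de = two_group_stats(gene_cohort.expression,
                             gene_cohort.metadata["class_label"])
        prognostic = {}
        for g in genes:
            evid = []
            row = de.loc[g]
            if row["t_p"] < 0.05:
                evid.append("hazardous" if row["mean_log2_diff"] > 0 else "protective")
            else:
                evid.append(None)
            for k, cid in enumerate(("XuLUAD", "LUAD")):
                evid.append(_survival_evidence(g, hazardous, protective, cid,
                                               config, prog_seed + k))
            prognostic[g] = prognostic_gene_call(g, evid)
        _write_json({g: c.category for g, c in prognostic.items()},
                    out / "prognostic_calls.json")
        list1, list2 = build_cmap_lists(prognostic, profiles)
        matrix_io.write_gene_lists(list1, out / "signatures")
        matrix_io.write_gene_lists(list2, out / "signatures")
        summary["stages"]["signature"] = {
            "list1_up": list1.up, "list1_down": list1.down,
            "list2_up": list2.up, "list2_down": list2.down,
        }
        summary["stages"]["prognostic"] = {
            g: c.category for g, c in prognostic.items()}
    except MirdxError as exc:
        stage = len(summary["stages"])
        raise MirdxError(f"pipeline halted after {stage} completed stage(s): {exc}"
                         ) from exc
    _write_json(summary, out / "summary.json")
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(),
                "files": sorted(p.name for p in out.iterdir() if p.is_file())}
    _write_json(manifest, out / "MANIFEST.json")
    return summary


def _gene_expression_cohort(hazardous, protective, background, seed):
    """Tumor/normal mRNA cohort with hazardous genes planted up, protective down."""
    spec = SimulationSpec(
        n_features=len(hazardous) + len(protective) + len(background),
        n_tumor=60, n_normal=30, n_paired=0,
        n_planted_up=len(hazardous), n_planted_down=len(protective),
        planted_log2fc=2.0, noise_sd=1.0, seed=seed)
    cohort = gen_expression_cohort(spec)
    names = hazardous + protective + background
    cohort.expression.index = pd.Index(names, name="feature_id")
    cohort.truth.index = pd.Index(names[: len(hazardous) + len(protective)],
                                  name="feature_id")
    return cohort


def _survival_evidence(gene, hazardous, protective, cohort_id, config, seed):
    """Directional survival evidence for one gene in one simulated cohort."""
    spec = SimulationSpec(n_features=1, n_tumor=config.survival_n, n_normal=0,
                          n_paired=0, n_planted_up=0, n_planted_down=0,
                          planted_log2fc=1.0, noise_sd=1.0,
                          seed=derive_seed(seed, f"{cohort_id}_{gene}"))
    c = gen_expression_cohort(spec)
    if gene in hazardous:
        beta = config.log_hr_per_unit
    elif gene in protective:
        beta = -config.log_hr_per_unit
    else:
        beta = 0.0
    meta = gen_survival(c, [c.expression.index[0]], beta, config.censor_rate,
                        derive_seed(seed, f"t_{cohort_id}_{gene}"))
    s = optimal_cutoff(c.expression.iloc[0], meta["time_months"],
                       meta["event"].astype(bool), cohort_id=cohort_id,
                       feature_id=gene)
    if s.logrank_p < 0.05:
        return "hazardous" if s.hr > 1 else "protective"
    return None
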
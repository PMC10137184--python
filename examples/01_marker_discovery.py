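"""Discover diagnostic miRNA markers in a synthetic tumor/normal cohort.

Builds a 200-feature cohort (87 tumors, 22 normals, 22 matched pairs) with
forty 4-fold planted markers, runs the unpaired and paired selection arms
(fold change > 2 or < 0.5, t-test p < 0.05, SAM permutation FDR < 0.05) and
unions them.
"""

from mirdx.markers import Thresholds, diff_stats, select_markers, union_marker_sets
from mirdx.simulate import SimulationSpec, gen_expression_cohort

cohort = gen_expression_cohort(SimulationSpec(seed=7))
groups = cohort.metadata["class_label"]

stats_unpaired = diff_stats(cohort.expression, groups, "unpaired",
                            Thresholds(), seed=7)
markers_unpaired = select_markers(stats_unpaired, provenance="unpaired_cohort")

paired_meta = cohort.metadata[cohort.metadata["pair_id"].notna()]
stats_paired = diff_stats(cohort.expression[paired_meta.index], groups,
                          "paired", Thresholds(), seed=8, metadata=paired_meta)
markers_paired = select_markers(stats_paired, provenance="paired_cohort")

markers = union_marker_sets(markers_unpaired, markers_paired)
planted = set(cohort.truth.index)
recovered = len(set(markers.index) & planted)

print(f"unpaired arm: {len(markers_unpaired)} markers")
print(f"paired arm:   {len(markers_paired)} markers")
print(f"union:        {len(markers)} unique markers")
print(f"recovered {recovered}/{len(planted)} planted features, "
      f"{len(markers) - recovered} false discoveries")
# The union is the diagnostic marker set; sensitivity near 1 and ~0 false
# discoveries show the three gates work together at these effect sizes.
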
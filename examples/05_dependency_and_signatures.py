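"""Normalize dependency screens and assemble connectivity-query gene lists.

Generates CRISPR and RNAi screens with essential / non-essential anchors and
per-line distortion, renormalizes each line so anchor medians land on -1 and
0, profiles per-gene dependence fractions, combines them with prognostic
calls, and writes the two up/down signature-list pairs as GRP files.
"""

import tempfile
from pathlib import Path

from mirdx.matrix_io import write_gene_lists
from mirdx.pharmaco import normalize_dependency, proliferation_profile
from mirdx.signatures import build_cmap_lists
from mirdx.simulate import gen_dependency_screen
from mirdx.survival import PrognosticGeneCall

hazardous = ["HAZ_BOTH", "HAZ_ONE"]
protective = ["PRO_MINOR", "PRO_ZERO"]
fractions = {"HAZ_BOTH": (0.8, 0.7), "HAZ_ONE": (0.8, 0.2),
             "PRO_MINOR": (0.3, 0.1), "PRO_ZERO": (0.0, 0.0)}
essential = [f"E{i}" for i in range(9)]
nonessential = [f"N{i}" for i in range(9)]

screens = []
for assay, idx in (("CRISPR", 0), ("RNAi", 1)):
    screen = gen_dependency_screen(
        n_genes=40, n_lines=30, essential_ids=essential,
        nonessential_ids=nonessential,
        dependent_ids={g: fractions[g][idx] for g in fractions},
        seed=11 if assay == "CRISPR" else 12, assay=assay)
    screens.append(normalize_dependency(screen))
    med = screen.normalized.loc[essential].median(axis=0)
    print(f"{assay}: essential-anchor median per line = {med.iloc[0]:.6f} "
          "(forced to -1 exactly)")

profiles = proliferation_profile(screens, list(fractions))
for g, p in profiles.items():
    print(f"{g:>10}: fractions {p.fraction_significant} -> {p.profile_class}")

prognostic = {g: PrognosticGeneCall(g, "hazardous", 2) for g in hazardous}
prognostic |= {g: PrognosticGeneCall(g, "protective", 2) for g in protective}
list1, list2 = build_cmap_lists(prognostic, profiles)
print(f"list 1: up {list1.up}, down {list1.down}")
print(f"list 2: up {list2.up}, down {list2.down}")

out = Path(tempfile.mkdtemp()) / "signatures"
paths = write_gene_lists(list1, out) + write_gene_lists(list2, out)
print("GRP files:", *[p.name for p in paths])
# list 1 pairs protective genes with little dependence against hazardous
# genes essential in most lines; list 2 relaxes both sides per its rules.
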
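"""Connectivity-query signature lists and result filtering.

Two up/down gene-list pairs are assembled from the prognostic calls and the
proliferation profiles of miRNA-targeted genes:

* list 1: up = protective genes with a significant dependence in < 50% of
  lines in *both* screening assays; down = hazardous genes affected in > 50%
  of lines in both assays.
* list 2: up = protective genes with *no* significant dependence in any line
  of either assay; down = hazardous genes affected in > 50% of lines in at
  least one assay.

Query execution against a connectivity database is out of scope; the lists are
written as GRP files and the result table (compound, score, p) is consumed
back for thresholding (score > 0.9, p <= 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .pharmaco import ProliferationProfile
from .survival import PrognosticGeneCall

log = logging.getLogger(__name__)


@dataclass
class SignatureLists:
    """Ordered up/down gene lists for a connectivity query."""

    label: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.up = list(dict.fromkeys(self.up))
        self.down = list(dict.fromkeys(self.down))
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down lists overlap: {sorted(overlap)}")


def build_cmap_lists(
    prognostic: Mapping[str, PrognosticGeneCall],
    proliferation: Mapping[str, ProliferationProfile],
) -> tuple[SignatureLists, SignatureLists]:
    """Assemble the two signature-list pairs from prognostic + dependence calls.

    Gene order follows the iteration order of ``prognostic`` (input order).
    Genes without a proliferation profile are skipped with a warning; genes
    whose prognostic call is ``neither`` never enter any list.
    """
    l1_up, l1_down, l2_up, l2_down = [], [], [], []
    skipped = 0
    for gene, call in prognostic.items():
        if call.category == "neither":
            continue
        prof = proliferation.get(gene)
        if prof is None:
            skipped += 1
            continue
        fr = list(prof.fraction_significant.values())
        minor_all = all(f < 0.5 for f in fr)
        if call.category == "protective":
            if minor_all:
                l1_up.append(gene)
            if prof.profile_class == "none_significant":
                l2_up.append(gene)
        elif call.category == "hazardous":
            if prof.profile_class == "both_major":
                l1_down.append(gene)
            if prof.profile_class in ("both_major", "either_major"):
                l2_down.append(gene)
    if skipped:
        log.warning("%d prognostic gene(s) lacked a proliferation profile", skipped)
    list1 = SignatureLists("cmap_list1", l1_up, l1_down)
    list2 = SignatureLists("cmap_list2", l2_up, l2_down)
    for lst in (list1, list2):
        if not lst.up or not lst.down:
            log.warning("%s has an empty side (up=%d, down=%d)",
                        lst.label, len(lst.up), len(lst.down))
    return list1, list2


def filter_connectivity(records: pd.DataFrame, score_min: float = 0.9,
                        p_max: float = 0.05) -> pd.DataFrame:
    """Retain connectivity records with score strictly above ``score_min`` and
    p at or below ``p_max``."""
    return records[(records["score"] > score_min) & (records["p"] <= p_max)].copy()
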
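"""scRNA-vs-reporter concordance summaries.

For one gene, classes called positive by the prior (fosmid) reporter
are bucketed by the *maximum* scRNA detection threshold they pass
(4 = detected at all four stringency levels).  Classes with scRNA
support but no reporter support, and vice versa, are listed separately.
The four threshold calls are inputs, never recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .evidence import EvidenceTable

__all__ = ["ConcordanceSummary", "concordance"]


@dataclass
class ConcordanceSummary:
    gene: str
    reporter_positive_classes: int
    agree_at_4: int
    agree_at_3: int
    agree_at_2: int
    agree_at_1: int
    scrna_only_classes: frozenset[str] = frozenset()
    reporter_only_classes: frozenset[str] = frozenset()
    caveat: str = ""

    @property
    def buckets(self) -> dict[int, int]:
        return {4: self.agree_at_4, 3: self.agree_at_3,
                2: self.agree_at_2, 1: self.agree_at_1}

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "reporter_positive_classes": self.reporter_positive_classes,
            "agree_at_4": self.agree_at_4,
            "agree_at_3": self.agree_at_3,
            "agree_at_2": self.agree_at_2,
            "agree_at_1": self.agree_at_1,
            "scrna_only_classes": sorted(self.scrna_only_classes),
            "reporter_only_classes": sorted(self.reporter_only_classes),
        }


def concordance(
    gene: str,
    ev: EvidenceTable,
    sex: str = "hermaphrodite",
    prior_modality: str = "fosmid_reporter",
) -> ConcordanceSummary:
    """Bucket prior-reporter-positive classes by max scRNA threshold passed.

    Buckets partition the reporter-positive set: each class counts in
    exactly one bucket (its maximum), so bucket totals plus the
    no-scRNA remainder equal the reporter-positive count.
    """
    reporter_pos: set[str] = set()
    scrna_max: dict[str, int] = {}
    for o in ev:
        if o.gene != gene or o.sex != sex or o.stage != "young_adult":
            continue
        if o.modality == prior_modality and o.level != "absent":
            reporter_pos.add(o.cell)
        elif o.modality == "scrna":
            scrna_max[o.cell] = max(scrna_max.get(o.cell, 0), o.scrna_threshold_pass or 0)

    if not scrna_max:
        warnings.warn(f"no scRNA rows for gene {gene}; buckets are empty", stacklevel=2)

    buckets = {1: 0, 2: 0, 3: 0, 4: 0}
    reporter_only: set[str] = set()
    for cell in reporter_pos:
        k = scrna_max.get(cell, 0)
        if k == 0:
            reporter_only.add(cell)
        else:
            buckets[k] += 1
    scrna_only = {c for c, k in scrna_max.items() if k > 0 and c not in reporter_pos}
    return ConcordanceSummary(
        gene=gene,
        reporter_positive_classes=len(reporter_pos),
        agree_at_4=buckets[4],
        agree_at_3=buckets[3],
        agree_at_2=buckets[2],
        agree_at_1=buckets[1],
        scrna_only_classes=frozenset(scrna_only),
        reporter_only_classes=frozenset(reporter_only),
    )
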
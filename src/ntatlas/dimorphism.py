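"""Sexual-dimorphism detection over sex-shared neuron classes.

Three dimorphism types are distinguished:

* ``on_off`` — a gene expressed in one sex and absent in the other
  (e.g. *unc-47* in ADF, PDB, PVN, PHC, AS10, AS11: male only);
* ``scaling`` — expressed in both sexes but at annotated different
  intensity (e.g. *eat-4* in PVN, stronger in males); requires the
  optional ordinal intensity annotation in the evidence, since the
  underlying image quantification is out of scope;
* ``switch`` — the assigned transmitter repertoire differs between
  sexes, one transmitter gained and another lost (e.g. AIM switching
  from glutamatergic to cholinergic in adult males).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .consensus import ConsensusCall
from .knowledge import KnowledgeBase, default_kb
from .rules import TransmitterAssignment

__all__ = ["DimorphismRecord", "detect_dimorphisms"]

_INTENSITY = {"low": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class DimorphismRecord:
    cell: str
    feature: str  # gene symbol, stain target, or "A->B" transmitter switch
    type: str  # on_off / scaling / switch
    higher_sex: str  # hermaphrodite / male / n/a
    note: str = ""


def _shared(kb: KnowledgeBase, cell: str) -> bool:
    try:
        cls, _ = kb.resolve_cell(cell)
    except KeyError:
        return False
    return cls.sex_scope == "shared"


def detect_dimorphisms(
    calls_h: Iterable[ConsensusCall],
    calls_m: Iterable[ConsensusCall],
    assignments_h: Iterable[TransmitterAssignment] = (),
    assignments_m: Iterable[TransmitterAssignment] = (),
    kb: KnowledgeBase | None = None,
) -> set[DimorphismRecord]:
    """Compare the two sexes' calls and assignments on shared classes."""
    kb = kb or default_kb()
    records: set[DimorphismRecord] = set()

    idx_h = {(c.gene, c.cell): c for c in calls_h if _shared(kb, c.cell)}
    idx_m = {(c.gene, c.cell): c for c in calls_m if _shared(kb, c.cell)}

    for key in sorted(set(idx_h) | set(idx_m)):
        gene, cell = key
        ch, cm = idx_h.get(key), idx_m.get(key)
        level_h = ch.level if ch else "absent"
        level_m = cm.level if cm else "absent"
        expr_h = level_h != "absent"
        expr_m = level_m != "absent"
        if expr_h != expr_m:
            records.add(DimorphismRecord(
                cell, gene, "on_off",
                "hermaphrodite" if expr_h else "male",
            ))
        elif expr_h and expr_m:
            ih = ch.intensity if ch else None
            im = cm.intensity if cm else None
            if ih is not None and im is not None and ih != im:
                records.add(DimorphismRecord(
                    cell, gene, "scaling",
                    "hermaphrodite" if _INTENSITY[ih] > _INTENSITY[im] else "male",
                ))

    # Transmitter switches: repertoire gained and lost between sexes.
    rep_h: dict[str, set[str]] = {}
    rep_m: dict[str, set[str]] = {}
    for a in assignments_h:
        if _shared(kb, a.cell):
            rep_h.setdefault(a.cell, set()).add(a.transmitter)
    for a in assignments_m:
        if _shared(kb, a.cell):
            rep_m.setdefault(a.cell, set()).add(a.transmitter)
    for cell in sorted(set(rep_h) | set(rep_m)):
        h = rep_h.get(cell, set())
        m = rep_m.get(cell, set())
        lost, gained = sorted(h - m), sorted(m - h)
        if lost and gained:
            sides = sorted(["/".join(lost), "/".join(gained)])
            records.add(DimorphismRecord(
                cell, f"{sides[0]}<->{sides[1]}", "switch", "n/a",
                note="transmitter lost and gained between sexes",
            ))
    return records


def dimorphism_frame(records: set[DimorphismRecord]):
    """Dimorphism records as a TSV-ready DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"cell": r.cell, "feature": r.feature, "type": r.type,
             "higher_sex": r.higher_sex, "note": r.note}
            for r in sorted(records, key=lambda r: (r.cell, r.feature, r.type))
        ],
        columns=["cell", "feature", "type", "higher_sex", "note"],
    )
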
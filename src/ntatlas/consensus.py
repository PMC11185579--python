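"""Multimodal evidence reconciliation.

Each (gene, cell, sex) triple with at least one observation is reduced
to a single :class:`ConsensusCall`.  The modality precedence encodes
the reliability ordering established by side-by-side comparisons of the
approaches: CRISPR knock-in reporter alleles outrank direct/antibody
staining, which outrank fosmid-based reporters, then promoter fusions,
then scRNA calls.  scRNA data is corroborating evidence only: on its
own it can establish ``present`` solely at 4/4 detection thresholds,
and never against an explicit reporter-allele ``absent`` row.

Missing triples are treated as ``absent`` downstream (closed world):
the printed tables are exhaustive for the in-scope loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evidence import EvidenceTable, ExpressionObservation
from .knowledge import KnowledgeBase

__all__ = ["ConsensusCall", "reconcile", "stain_status", "call_index", "consensus_frame"]

#: Precedence groups, highest first.  Ties inside a group are combined.
PRECEDENCE: tuple[tuple[str, ...], ...] = (
    ("reporter_allele",),
    ("direct_stain", "antibody_stain"),
    ("fosmid_reporter",),
    ("promoter_transgene",),
    ("scrna",),
)

_LEVEL_ORDER = {"absent": 0, "variable_dim": 1, "present": 2}


@dataclass(frozen=True)
class ConsensusCall:
    gene: str
    cell: str
    sex: str
    level: str
    supporting_modalities: frozenset[str]
    conflict: bool = False
    conflict_note: str = ""
    intensity: str | None = None

    @property
    def expressed(self) -> bool:
        return self.level in ("present", "variable_dim")


def _combine_group(rows: list[ExpressionObservation]) -> str:
    """Within one precedence group, the strongest call wins."""
    return max((r.level for r in rows), key=_LEVEL_ORDER.__getitem__)


def reconcile(ev: EvidenceTable, kb: KnowledgeBase | None = None) -> list[ConsensusCall]:
    """Reconcile an evidence table into one call per (gene, cell, sex).

    A pure function of the observation *set*: row order never matters.
    Young-adult observations only; larval rows are excluded from
    classification by design.
    """
    groups: dict[tuple[str, str, str], list[ExpressionObservation]] = {}
    for obs in ev:
        if obs.stage != "young_adult":
            continue
        groups.setdefault((obs.gene, obs.cell, obs.sex), []).append(obs)

    calls: list[ConsensusCall] = []
    for (gene, cell, sex), rows in sorted(groups.items()):
        by_modality: dict[str, list[ExpressionObservation]] = {}
        for r in rows:
            by_modality.setdefault(r.modality, []).append(r)

        level = None
        deciding: tuple[str, ...] = ()
        for group in PRECEDENCE:
            present_rows = [r for m in group for r in by_modality.get(m, [])]
            if present_rows:
                level = _combine_group(present_rows)
                deciding = group
                break
        assert level is not None

        # scRNA alone: 'present' requires all four thresholds passed.
        if deciding == ("scrna",) and level == "present":
            max_pass = max(r.scrna_threshold_pass or 0 for r in by_modality["scrna"])
            if max_pass < 4:
                level = "variable_dim"

        # Conflict bookkeeping: reporter allele vs any other modality
        # disagreeing on absent-vs-expressed.
        conflict = False
        note = ""
        reporter_rows = by_modality.get("reporter_allele", [])
        if reporter_rows:
            rep_expressed = _combine_group(reporter_rows) != "absent"
            for modality in (m for group in PRECEDENCE[1:] for m in group):
                mrows = by_modality.get(modality)
                if not mrows:
                    continue
                other_expressed = _combine_group(mrows) != "absent"
                if other_expressed != rep_expressed:
                    conflict = True
                    note = (
                        f"reporter allele {'expressed' if rep_expressed else 'absent'} "
                        f"but {modality} {'expressed' if other_expressed else 'absent'}"
                    )
                    break

        intensities = [r.intensity for r in rows if r.intensity is not None]
        ordinal = {"low": 0, "medium": 1, "high": 2}
        intensity = max(intensities, key=ordinal.__getitem__) if intensities else None

        calls.append(
            ConsensusCall(
                gene=gene,
                cell=cell,
                sex=sex,
                level=level,
                supporting_modalities=frozenset(
                    m for m, mrows in by_modality.items()
                    if _combine_group(mrows) != "absent"
                ),
                conflict=conflict,
                conflict_note=note,
                intensity=intensity,
            )
        )
    return calls


def call_index(calls: list[ConsensusCall]) -> dict[tuple[str, str, str], ConsensusCall]:
    return {(c.gene, c.cell, c.sex): c for c in calls}


_STAIN_OF = {"GABA": "GABA", "5-HT": "5-HT", "DA": "DA"}


def stain_status(ev: EvidenceTable, cell: str, sex: str, transmitter: str) -> str:
    """Staining status for a transmitter in one cell: positive/negative/unknown.

    Consults direct-staining and antibody-staining observations only.
    """
    if transmitter not in _STAIN_OF:
        raise KeyError(f"no staining channel for transmitter {transmitter!r}")
    target = _STAIN_OF[transmitter]
    rows = [
        o for o in ev
        if o.is_stain and o.gene == target and o.cell == cell and o.sex == sex
        and o.stage == "young_adult"
    ]
    if not rows:
        return "unknown"
    level = _combine_group(rows)
    return "positive" if level != "absent" else "negative"


def consensus_frame(calls: list[ConsensusCall]):
    """Consensus calls as a DataFrame (TSV-ready, with conflict columns)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "cell": c.cell,
                "sex": c.sex,
                "level": c.level,
                "supporting_modalities": ",".join(sorted(c.supporting_modalities)),
                "conflict": c.conflict,
                "conflict_note": c.conflict_note,
                "intensity": c.intensity or "",
            }
            for c in sorted(calls, key=lambda c: (c.gene, c.cell, c.sex))
        ]
    )
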
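"""Atlas-level summaries: transmitter-system proportions and census queries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .consensus import ConsensusCall
from .knowledge import KnowledgeBase, default_kb
from .rules import TransmitterAssignment, cotransmission_profile

__all__ = [
    "AtlasSummary",
    "summarize_atlas",
    "cat1_only_classes",
    "tbh1_only_classes",
    "betaine_uptake_release_classes",
]

_MONOAMINES = frozenset(
    {"5-HT", "DA", "TA", "OA", "betaine", "PEOH_candidate",
     "bas1_unknown_MA", "unknown_MA"}
)


@dataclass
class AtlasSummary:
    sex: str
    total_neurons: int
    counts: dict[str, int]
    fractions: dict[str, float]
    class_counts: dict[str, int]
    cotransmission_histogram: dict[int, int]
    lower_bound: bool = False

    def as_dict(self) -> dict:
        return {
            "sex": self.sex,
            "total_neurons": self.total_neurons,
            "counts": self.counts,
            "fractions": self.fractions,
            "class_counts": self.class_counts,
            "cotransmission_histogram": self.cotransmission_histogram,
            "lower_bound": self.lower_bound,
        }


def _neuron_tally(
    assignments: Iterable[TransmitterAssignment],
    kb: KnowledgeBase,
    sex: str,
    pred,
) -> tuple[int, int]:
    """(member-expanded neuron count, class count) of cells matching pred."""
    neurons = 0
    classes: set[str] = set()
    seen: set[tuple] = set()
    for a in assignments:
        if a.sex != sex or not pred(a):
            continue
        try:
            cls, member = kb.resolve_cell(a.cell)
        except KeyError:
            cls, member = None, None
        if cls is None or cls.kind != "neuron":
            continue
        key = (cls.name, member)
        if key in seen:
            continue
        seen.add(key)
        neurons += 1 if member is not None else cls.members_per_sex
        classes.add(cls.name)
    return neurons, len(classes)


def summarize_atlas(
    assignments: Iterable[TransmitterAssignment],
    kb: KnowledgeBase | None = None,
    sex: str = "hermaphrodite",
    calls: Iterable[ConsensusCall] | None = None,
) -> AtlasSummary:
    """Fractions of neurons per primary transmitter system.

    Glutamatergic = a Glu assignment (*eat-4*); cholinergic = ACh
    (*unc-17*); GABA-synthesizing = GABA with synthesis (*unc-25*);
    monoaminergic = any monoamine assignment with vesicular release
    (*cat-1*).  Counts are member-expanded over the KB census.  If the
    input covers only part of the census the proportions are flagged as
    lower bounds; pass the consensus ``calls`` as well so classes whose
    every call is negative (orphan candidates) count as covered.
    """
    kb = kb or default_kb()
    assignments = [a for a in assignments if a.sex == sex]
    total = kb.neuron_total(sex)

    preds = {
        "glutamatergic": lambda a: a.transmitter == "Glu",
        "cholinergic": lambda a: a.transmitter == "ACh",
        "GABA_synthesizing": lambda a: a.transmitter == "GABA" and a.synthesizes,
        "monoaminergic": lambda a: (
            a.transmitter in _MONOAMINES and a.vesicular_release
        ),
    }
    counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for name, pred in preds.items():
        counts[name], class_counts[name] = _neuron_tally(assignments, kb, sex, pred)
    fractions = {k: v / total if total else 0.0 for k, v in counts.items()}

    covered: set[str] = set()
    coverage_source = list(calls) if calls is not None else assignments
    for item in coverage_source:
        if getattr(item, "sex", sex) != sex:
            continue
        try:
            covered.add(kb.resolve_cell(item.cell)[0].name)
        except KeyError:
            pass
    census = {c.name for c in kb.neuron_classes(sex)}
    lower_bound = not census <= covered

    per_cell, tally = cotransmission_profile(assignments, sex)
    histogram: dict[int, int] = {}
    for n in per_cell.values():
        histogram[n] = histogram.get(n, 0) + 1
    return AtlasSummary(
        sex=sex,
        total_neurons=total,
        counts=counts,
        fractions=fractions,
        class_counts=class_counts,
        cotransmission_histogram=dict(sorted(histogram.items())),
        lower_bound=lower_bound,
    )


_MA_PARTNERS = ("tph-1", "cat-2", "bas-1", "tdc-1", "tbh-1",
                "mod-5", "snf-3", "oct-1", "hdl-1")


def _profiles(calls: Iterable[ConsensusCall], kb: KnowledgeBase):
    by: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        if c.expressed and c.gene not in ("5-HT", "GABA", "DA"):
            by.setdefault((c.cell, c.sex), set()).add(c.gene)
    return by


def cat1_only_classes(calls: Iterable[ConsensusCall], kb: KnowledgeBase | None = None) -> set[str]:
    """Neuron classes expressing cat-1/VMAT but no other monoamine pathway gene."""
    kb = kb or default_kb()
    out: set[str] = set()
    for (cell, _sex), genes in _profiles(calls, kb).items():
        try:
            cls, _ = kb.resolve_cell(cell)
        except KeyError:
            continue
        if cls.kind == "neuron" and "cat-1" in genes and not (genes & set(_MA_PARTNERS)):
            out.add(cls.name)
    return out


def tbh1_only_classes(calls: Iterable[ConsensusCall], kb: KnowledgeBase | None = None) -> set[str]:
    """Neuron classes with tbh-1 and no other monoaminergic pathway gene."""
    kb = kb or default_kb()
    ma = set(_MA_PARTNERS) | {"cat-1"}
    out: set[str] = set()
    for (cell, _sex), genes in _profiles(calls, kb).items():
        try:
            cls, _ = kb.resolve_cell(cell)
        except KeyError:
            continue
        if cls.kind == "neuron" and genes & ma == {"tbh-1"}:
            out.add(cls.name)
    return out


def betaine_uptake_release_classes(
    assignments: Iterable[TransmitterAssignment],
    kb: KnowledgeBase | None = None,
    sex: str = "hermaphrodite",
) -> set[str]:
    """Classes positioned for betaine signaling (snf-3 uptake + cat-1
    release) without canonical monoamine synthesis."""
    kb = kb or default_kb()
    by_cell: dict[str, list[TransmitterAssignment]] = {}
    for a in assignments:
        if a.sex == sex:
            by_cell.setdefault(a.cell, []).append(a)
    out: set[str] = set()
    for cell, al in by_cell.items():
        betaine = next((a for a in al if a.transmitter == "betaine"), None)
        if betaine is None or not betaine.vesicular_release:
            continue
        if any(a.synthesizes and a.transmitter in ("5-HT", "DA", "TA", "OA")
               for a in al):
            continue
        try:
            out.add(kb.resolve_cell(cell)[0].name)
        except KeyError:
            out.add(cell)
    return out
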
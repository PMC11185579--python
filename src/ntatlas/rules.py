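"""Neurotransmitter identity rule engine.

Derives per-(cell, sex, transmitter) mode flags — synthesis, uptake,
vesicular release, staining support, unconventional acquisition — from
consensus expression calls, and composes a category label per cell.

The rules implement the combinatorial marker-gene logic of the field:

* glutamate: *eat-4*/VGLUT expression alone is sufficient;
* acetylcholine: *unc-17*/VAChT (ACh synthesis via *cha-1* is implied
  by the shared operon);
* GABA: synthesis via *unc-25*/GAD; uptake neurons stain anti-GABA
  without *unc-25* and carry an uptake route (*snf-11*) or recycle via
  *unc-47*/VGAT; *unc-47* without any GABA evidence flags an unknown
  VGAT substrate;
* monoamines: serotonin needs *tph-1* + *bas-1*, dopamine *cat-2* +
  *bas-1*, tyramine *tdc-1* (without *tbh-1*), octopamine *tdc-1* +
  *tbh-1*; all release via *cat-1*/VMAT; uptake via *mod-5* (5-HT),
  *oct-1* (tyramine) and *snf-3* (betaine);
* partial pathways flag candidate novel transmitters: *tph-1* without
  *bas-1* (5-HTP), *bas-1* + *tbh-1* without *tdc-1* (PEOH?), *bas-1*
  without any substrate-supplying enzyme (bas-1-dependent unknown
  monoamine), *tbh-1* alone or *cat-1* alone (unknown monoamine).

``variable_dim`` counts as expressed throughout, but propagates into a
``dim_variable`` confidence flag and a ``*`` suffix on labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .consensus import ConsensusCall
from .evidence import EvidenceTable
from .knowledge import KnowledgeBase, default_kb

__all__ = [
    "TransmitterAssignment",
    "CategoryLabel",
    "assign_transmitters",
    "assign_profile",
    "categorize",
    "find_orphans",
    "cotransmission_profile",
    "subclass_partition",
    "normalize_printed_label",
    "CLASSIFICATION_GENES",
    "VESICULAR_GENES",
]

#: The ten gene-level classification loci of the core rule grid.
CLASSIFICATION_GENES = (
    "eat-4", "unc-17", "unc-25", "unc-47", "cat-1",
    "tph-1", "cat-2", "bas-1", "tdc-1", "tbh-1",
)
UPTAKE_GENES = ("mod-5", "snf-3", "oct-1", "snf-11")
VESICULAR_GENES = ("eat-4", "unc-17", "unc-47", "cat-1")


@dataclass(frozen=True)
class TransmitterAssignment:
    cell: str
    sex: str
    transmitter: str
    synthesizes: bool = False
    uptakes: bool = False
    vesicular_release: bool = False
    stain_supported: str = "unknown"  # positive / negative / unknown
    unconventional_acquisition: bool = False
    confidence: str = "robust"  # robust / dim_variable
    evidence_refs: tuple[str, ...] = ()

    @property
    def flags(self) -> tuple:
        """Mode-flag signature used by equivalence tests."""
        return (
            self.transmitter,
            self.synthesizes,
            self.uptakes,
            self.vesicular_release,
            self.unconventional_acquisition,
        )


@dataclass(frozen=True)
class CategoryLabel:
    cell: str
    sex: str
    label: str
    kind: str = "neuron"


Level = str
_EXPRESSED = ("present", "variable_dim")


class _Profile:
    """Per-cell view over gene levels and stain statuses."""

    def __init__(self, levels: Mapping[str, Level], stains: Mapping[str, Level]):
        self.levels = dict(levels)
        self.stains = dict(stains)
        self._used: set[str] = set()

    def expr(self, gene: str) -> bool:
        ok = self.levels.get(gene, "absent") in _EXPRESSED
        if ok:
            self._used.add(gene)
        return ok

    def dim_of(self, *genes: str) -> bool:
        return any(self.levels.get(g) == "variable_dim" for g in genes)

    def stain(self, target: str) -> str:
        level = self.stains.get(target)
        if level is None:
            return "unknown"
        return "positive" if level in _EXPRESSED else "negative"

    def stain_dim(self, target: str) -> bool:
        return self.stains.get(target) == "variable_dim"


def assign_profile(
    levels: Mapping[str, Level],
    stains: Mapping[str, Level] | None = None,
    cell: str = "",
    sex: str = "hermaphrodite",
) -> list[TransmitterAssignment]:
    """Apply the full rule set to a single cell's gene-level profile.

    ``levels`` maps gene symbols to tri-level calls (missing = absent);
    ``stains`` maps staining targets ("GABA", "5-HT", "DA") to levels.
    """
    p = _Profile(levels, stains or {})
    out: list[TransmitterAssignment] = []

    def emit(transmitter, *, synth=False, uptake=False, release=False,
             stain="unknown", unconventional=False, dim=False, refs=()):
        out.append(TransmitterAssignment(
            cell=cell, sex=sex, transmitter=transmitter,
            synthesizes=synth, uptakes=uptake, vesicular_release=release,
            stain_supported=stain, unconventional_acquisition=unconventional,
            confidence="dim_variable" if dim else "robust",
            evidence_refs=tuple(refs),
        ))

    # --- fast amino-acid transmitters -------------------------------
    if p.expr("eat-4"):
        emit("Glu", synth=True, release=True,
             dim=p.dim_of("eat-4"), refs=("eat-4",))
    if p.expr("unc-17"):
        emit("ACh", synth=True, release=True,
             dim=p.dim_of("unc-17"), refs=("unc-17",))

    gaba_stain = p.stain("GABA")
    gaba_synth = p.expr("unc-25")
    unc47 = p.expr("unc-47")
    if gaba_synth or gaba_stain == "positive":
        uptake = (
            gaba_stain == "positive"
            and not gaba_synth
            and (p.expr("snf-11") or unc47)
        )
        unconventional = (
            gaba_stain == "positive" and not gaba_synth and not uptake
        )
        refs = [g for g in ("unc-25", "unc-47", "snf-11") if p.expr(g)]
        emit("GABA", synth=gaba_synth, uptake=uptake, release=unc47,
             stain=gaba_stain, unconventional=unconventional,
             dim=p.dim_of(*refs) or p.stain_dim("GABA"), refs=refs)
    elif unc47:
        # VGAT without GABA synthesis or staining: unknown substrate.
        emit("unknown_VGAT_substrate", release=True, stain=gaba_stain,
             dim=p.dim_of("unc-47"), refs=("unc-47",))

    # --- serotonin pathway -------------------------------------------
    ht_stain = p.stain("5-HT")
    ht_synth = p.expr("tph-1") and p.expr("bas-1")
    ht_uptake = p.expr("mod-5")
    cat1 = p.expr("cat-1")
    if ht_synth or ht_uptake or ht_stain == "positive":
        refs = [g for g in ("tph-1", "bas-1", "mod-5", "cat-1") if p.expr(g)]
        emit("5-HT", synth=ht_synth, uptake=ht_uptake, release=cat1,
             stain=ht_stain,
             unconventional=(ht_stain == "positive" and not ht_synth and not ht_uptake),
             dim=p.dim_of(*refs) or p.stain_dim("5-HT"), refs=refs)
    if p.expr("tph-1") and not p.expr("bas-1"):
        emit("5-HTP", synth=True, dim=p.dim_of("tph-1"), refs=("tph-1",))

    # --- catecholamine / trace-amine pathways ------------------------
    da_stain = p.stain("DA")
    da_synth = p.expr("cat-2") and p.expr("bas-1")
    if da_synth or da_stain == "positive":
        refs = [g for g in ("cat-2", "bas-1", "cat-1") if p.expr(g)]
        emit("DA", synth=da_synth, release=cat1, stain=da_stain,
             unconventional=(da_stain == "positive" and not da_synth),
             dim=p.dim_of(*refs), refs=refs)

    tdc = p.expr("tdc-1")
    tbh = p.expr("tbh-1")
    ta_synth = tdc and not tbh
    ta_uptake = p.expr("oct-1")
    if ta_synth or ta_uptake:
        refs = [g for g in ("tdc-1", "oct-1", "cat-1") if p.expr(g)]
        emit("TA", synth=ta_synth, uptake=ta_uptake, release=cat1,
             dim=p.dim_of(*refs), refs=refs)
    if tdc and tbh:
        refs = [g for g in ("tdc-1", "tbh-1", "cat-1") if p.expr(g)]
        emit("OA", synth=True, release=cat1, dim=p.dim_of(*refs), refs=refs)

    if p.expr("snf-3"):
        refs = [g for g in ("snf-3", "cat-1") if p.expr(g)]
        emit("betaine", uptake=True, release=cat1,
             dim=p.dim_of(*refs), refs=refs)

    # --- candidate novel monoamines ----------------------------------
    bas = p.expr("bas-1")
    if bas and tbh and not tdc:
        refs = [g for g in ("bas-1", "tbh-1", "cat-1") if p.expr(g)]
        emit("PEOH_candidate", synth=True, release=cat1,
             dim=p.dim_of(*refs), refs=refs)
    if bas and not p.expr("tph-1") and not p.expr("cat-2") and not tbh:
        refs = [g for g in ("bas-1", "cat-1") if p.expr(g)]
        emit("bas1_unknown_MA", synth=True, release=cat1,
             dim=p.dim_of(*refs), refs=refs)
    # cat-1 with no synthesis route and no uptake transporter: the
    # transporter may carry a monoamine yet to be discovered.
    enzymes = ("tph-1", "cat-2", "bas-1", "tdc-1", "tbh-1")
    if cat1 and not any(p.expr(g) for g in enzymes) and not any(
        p.expr(g) for g in ("mod-5", "snf-3", "oct-1")
    ):
        emit("unknown_MA", release=True, dim=p.dim_of("cat-1"), refs=("cat-1",))
    # tbh-1 without its substrate-supplying tdc-1 and without bas-1:
    # non-canonical synthesis (5-HT uptake via mod-5, when present,
    # accounts for the amine content instead).
    if tbh and not tdc and not bas and not p.expr("mod-5"):
        refs = [g for g in ("tbh-1", "cat-1") if p.expr(g)]
        emit("unknown_MA", synth=False, release=cat1,
             dim=p.dim_of(*refs), refs=refs)

    # Merge duplicate unknown_MA emissions (possible only when both
    # triggers fire; keep the strongest flags).
    seen: dict[str, TransmitterAssignment] = {}
    merged: list[TransmitterAssignment] = []
    for a in out:
        if a.transmitter in seen:
            prev = seen[a.transmitter]
            keep = TransmitterAssignment(
                cell=a.cell, sex=a.sex, transmitter=a.transmitter,
                synthesizes=prev.synthesizes or a.synthesizes,
                uptakes=prev.uptakes or a.uptakes,
                vesicular_release=prev.vesicular_release or a.vesicular_release,
                stain_supported=prev.stain_supported,
                unconventional_acquisition=prev.unconventional_acquisition
                or a.unconventional_acquisition,
                confidence=("dim_variable"
                            if "dim_variable" in (prev.confidence, a.confidence)
                            else "robust"),
                evidence_refs=tuple(dict.fromkeys(prev.evidence_refs + a.evidence_refs)),
            )
            merged[merged.index(prev)] = keep
            seen[a.transmitter] = keep
        else:
            seen[a.transmitter] = a
            merged.append(a)
    return merged


def _profiles_from_calls(
    calls: Iterable[ConsensusCall],
) -> dict[tuple[str, str], tuple[dict, dict]]:
    cells: dict[tuple[str, str], tuple[dict, dict]] = {}
    for c in calls:
        levels, stains = cells.setdefault((c.cell, c.sex), ({}, {}))
        if c.gene in ("5-HT", "GABA", "DA"):
            stains[c.gene] = c.level
        else:
            levels[c.gene] = c.level
    return cells


def assign_transmitters(
    calls: Iterable[ConsensusCall], kb: KnowledgeBase | None = None
) -> list[TransmitterAssignment]:
    """Rule-engine entry point over a set of consensus calls.

    Calls referencing glia or non-neuronal cells are classified with the
    same rules (their kind is recorded by :func:`categorize`), never
    dropped.
    """
    kb = kb or default_kb()
    out: list[TransmitterAssignment] = []
    for (cell, sex), (levels, stains) in sorted(_profiles_from_calls(calls).items()):
        out.extend(assign_profile(levels, stains, cell=cell, sex=sex))
    return out


# ---------------------------------------------------------------------
# Category labels

#: Canonical component order for composed labels.
_COMPONENT_ORDER = [
    "Glu", "ACh", "GABA", "GABA (uptake)",
    "GABA (alternative synthesis/uptake mechanism?)",
    "5-HTP",
    "5-HT", "5-HT (& uptake)", "5-HT (uptake)",
    "5-HT (alternative synthesis/uptake mechanism?)",
    "dopamine", "tyramine", "tyramine (+ uptake)", "tyramine (uptake)",
    "octopamine", "PEOH?", "bas-1-depen-unknown monoamine?",
    "unknown monoamine?", "betaine (uptake)", "unknown VGAT substrate?",
]
_ORDER_INDEX = {c: i for i, c in enumerate(_COMPONENT_ORDER)}


def _component(a: TransmitterAssignment) -> str | None:
    t = a.transmitter
    if t == "Glu":
        return "Glu"
    if t == "ACh":
        return "ACh"
    if t == "GABA":
        if a.synthesizes:
            return "GABA"
        if a.uptakes:
            return "GABA (uptake)"
        return "GABA (alternative synthesis/uptake mechanism?)"
    if t == "5-HT":
        # Synthesis dominates; uptake-in-addition stays in the flags
        # (the printed "(& uptake)" annotation is redundant with the
        # mod-5 column and not applied consistently).
        if a.synthesizes:
            return "5-HT"
        if a.uptakes:
            return "5-HT (uptake)"
        return "5-HT (alternative synthesis/uptake mechanism?)"
    if t == "5-HTP":
        return "5-HTP"
    if t == "DA":
        return "dopamine"
    if t == "TA":
        if a.synthesizes and a.uptakes:
            return "tyramine (+ uptake)"
        if a.synthesizes:
            return "tyramine"
        return "tyramine (uptake)"
    if t == "OA":
        return "octopamine"
    if t == "betaine":
        return "betaine (uptake)"
    if t == "PEOH_candidate":
        return "PEOH?"
    if t == "bas1_unknown_MA":
        return "bas-1-depen-unknown monoamine?"
    if t == "unknown_MA":
        return "unknown monoamine?"
    if t == "unknown_VGAT_substrate":
        return "unknown VGAT substrate?"
    return None


def categorize(
    assignments: Iterable[TransmitterAssignment],
    kb: KnowledgeBase | None = None,
    cell: str | None = None,
    sex: str | None = None,
    monoamine_only: bool = False,
) -> CategoryLabel:
    """Compose the category label for one cell's assignment set.

    Components are joined with " + " in canonical order; a trailing
    "*" marks labels any of whose supporting genes were dim/variable.
    With ``monoamine_only`` the fast-transmitter and VGAT components
    are suppressed, matching the scope of the monoamine category table.
    """
    kb = kb or default_kb()
    assignments = list(assignments)
    if assignments:
        cell = cell or assignments[0].cell
        sex = sex or assignments[0].sex
    if cell is None:
        raise ValueError("cell required for an empty assignment set")
    sex = sex or "hermaphrodite"
    try:
        kind = kb.resolve_cell(cell)[0].kind
    except KeyError:
        kind = "neuron"  # permissive / synthetic cells

    skip = {"Glu", "ACh", "GABA", "GABA (uptake)",
            "GABA (alternative synthesis/uptake mechanism?)",
            "unknown VGAT substrate?"} if monoamine_only else set()
    parts: list[tuple[int, str, bool]] = []
    for a in assignments:
        comp = _component(a)
        if comp is None or comp in skip:
            continue
        parts.append((_ORDER_INDEX[comp], comp, a.confidence == "dim_variable"))
    parts.sort()
    if not parts:
        label = "orphan/neuropeptidergic" if kind == "neuron" else f"none ({kind})"
        return CategoryLabel(cell, sex, label, kind)
    label = " + ".join(c for _, c, _d in parts)
    if any(d for _, _c, d in parts):
        label += "*"
    return CategoryLabel(cell, sex, label, kind)


#: Spelling map applied to printed label components before comparison.
_PRINTED_COMPONENT_MAP = {
    "5-HTP (synthesis)": "5-HTP",
    "5-HT (& uptake)": "5-HT",
}


def normalize_printed_label(printed: str, starred: bool = False) -> str:
    """Map a printed free-text category label to the canonical grammar.

    Splits on "+"/"and" joiners, normalizes component spellings,
    reorders canonically and rejoins; ``starred`` appends the dim
    marker the printed tables attach to the neuron name instead.
    """
    text = printed.replace(" and ", " + ")
    parts = []
    depth = 0
    current = []
    for ch in text:
        depth += ch == "("
        depth -= ch == ")"
        if ch == "+" and depth == 0:
            parts.append("".join(current))
            current = []
        else:
            current.append(ch)
    parts.append("".join(current))
    comps = []
    for raw in parts:
        comp = " ".join(raw.split())
        comp = _PRINTED_COMPONENT_MAP.get(comp, comp)
        comps.append(comp)
    comps.sort(key=lambda c: _ORDER_INDEX.get(c, len(_ORDER_INDEX)))
    label = " + ".join(comps)
    return label + "*" if starred else label


# ---------------------------------------------------------------------
# Atlas-level queries

def find_orphans(
    assignments: Iterable[TransmitterAssignment],
    calls: Iterable[ConsensusCall],
    kb: KnowledgeBase | None = None,
    sex: str = "hermaphrodite",
    male_specific_only: bool = False,
) -> set[str]:
    """Neuron classes expressing none of the four vesicular transporters.

    Requires full-atlas coverage; partial coverage triggers a warning
    (the result is then only a statement about the covered classes).
    """
    kb = kb or default_kb()
    expressed_vesicular: set[str] = set()
    covered: set[str] = set()
    for c in calls:
        if c.sex != sex or c.gene in ("5-HT", "GABA", "DA"):
            continue
        try:
            cls, _ = kb.resolve_cell(c.cell)
        except KeyError:
            continue
        covered.add(cls.name)
        if c.gene in VESICULAR_GENES and c.expressed:
            expressed_vesicular.add(cls.name)
    census = {c.name for c in kb.neuron_classes(sex)}
    if not census <= covered:
        warnings.warn(
            f"orphan scan on partial coverage: {len(census - covered)} "
            f"{sex} neuron classes carry no observation; closed-world "
            "absence applied to them",
            stacklevel=2,
        )
    pool = census - expressed_vesicular
    if male_specific_only:
        pool = {
            n for n in pool if kb.cell_classes[n].sex_scope == "male_specific"
        }
    return pool


def cotransmission_profile(
    assignments: Iterable[TransmitterAssignment], sex: str | None = None
) -> tuple[dict[str, int], dict[frozenset[str], int]]:
    """Released-transmitter count per cell and tally per combination.

    Only ``vesicular_release=True`` assignments count as released.
    """
    per_cell: dict[str, set[str]] = {}
    for a in assignments:
        if sex is not None and a.sex != sex:
            continue
        per_cell.setdefault(a.cell, set())
        if a.vesicular_release:
            per_cell[a.cell].add(a.transmitter)
    counts = {cell: len(ts) for cell, ts in per_cell.items()}
    tally: dict[frozenset[str], int] = {}
    for ts in per_cell.values():
        if ts:
            key = frozenset(ts)
            tally[key] = tally.get(key, 0) + 1
    return counts, tally


def subclass_partition(
    ev: EvidenceTable, class_prefix: str, kb: KnowledgeBase | None = None
) -> list[tuple[tuple, list[str]]]:
    """Partition the members of a neuron class by exact expression profile.

    Groups the individually named members of ``class_prefix`` (e.g.
    "CA", "CP") into equivalence classes under identical
    (gene-or-stain → level) profiles; unobserved genes count as absent.
    Returns ``[(profile, [cells...]), ...]`` sorted by first member.
    """
    kb = kb or default_kb()
    from .consensus import reconcile

    calls = reconcile(ev, kb)
    members: dict[str, dict[str, str]] = {}
    for c in calls:
        try:
            cls, member = kb.resolve_cell(c.cell)
        except KeyError:
            cls, member = None, None
        if cls is not None and cls.name == class_prefix and member is not None:
            members.setdefault(c.cell, {})[c.gene] = c.level
        elif cls is None and c.cell.startswith(class_prefix):
            members.setdefault(c.cell, {})[c.gene] = c.level
    all_genes = sorted({g for prof in members.values() for g in prof})
    groups: dict[tuple, list[str]] = {}
    for cell, prof in members.items():
        key = tuple((g, prof.get(g, "absent")) for g in all_genes)
        key = tuple((g, lv) for g, lv in key if lv != "absent") or (("(none)", "absent"),)
        groups.setdefault(key, []).append(cell)
    out = [(k, sorted(v)) for k, v in groups.items()]
    out.sort(key=lambda kv: kv[1][0])
    return out
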
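"""Fixture encodings of the printed summary tables.

Three printed artefacts are shipped as code-defined evidence tables:

* ``fixture_table1`` — the monoamine *uptake* table (serotonin,
  tyramine and betaine sections; anti-5-HT staining status).
* ``fixture_table2`` — the category table for monoaminergic pathway
  genes: nine gene columns (+ / − / dim-variable) per neuron class,
  plus the direct-staining column.
* ``fixture_fig10c`` — the per-neuron profiles of the male ventral-cord
  CA and CP neurons (CA1-CA9, CP0-CP9) over the classic transmitter
  pathway genes and 5-HT/GABA staining.

Encoding conventions: the printed tables use ``+``, ``−``, ``+/−`` and
a ``*`` footnote for dim-and-variable expression; both ``+/−`` and
``*``-flagged entries map to ``variable_dim``.  Ranges like "CP1–6" and
"VB1–11" are expanded to one observation per listed class member;
"PVW (m)" becomes a male-only row.  Empty printed cells emit no row
(the consensus layer treats missing rows as absent).
"""

from __future__ import annotations

from .evidence import EvidenceTable, ExpressionObservation
from .knowledge import KnowledgeBase, default_kb

__all__ = [
    "fixture_table1",
    "fixture_table2",
    "fixture_fig10c",
    "table2_expectations",
    "TABLE2_GENES",
]

#: Gene column order of the category table.
TABLE2_GENES = (
    "cat-1", "tph-1", "cat-2", "bas-1", "tdc-1", "tbh-1", "mod-5", "snf-3", "oct-1",
)


def _expand(cells):
    """'CP1-6' -> CP1..CP6 etc.; plain names pass through."""
    out = []
    for token in cells:
        if "-" in token and token[-1].isdigit():
            stem = token.rstrip("0123456789-")
            lo, hi = token[len(stem):].split("-")
            out.extend(f"{stem}{i}" for i in range(int(lo), int(hi) + 1))
        else:
            out.append(token)
    return out


def _sexes_for(kb: KnowledgeBase, cell: str, male_only: bool = False):
    cls, _ = kb.resolve_cell(cell)
    if male_only:
        return ("male",)
    if cls.sex_scope == "male_specific":
        return ("male",)
    if cls.sex_scope == "hermaphrodite_specific":
        return ("hermaphrodite",)
    return ("hermaphrodite", "male")


# ---------------------------------------------------------------------
# Category table: monoaminergic expression patterns per class.
#
# Each row: (printed label, gene levels over TABLE2_GENES as a string of
# {+,-,.} where '.' is a blank printed cell, staining target or None,
# cells with star flags, dim-gene resolution).  Cells are (name, starred)
# pairs; `dim` maps a cell to the genes whose '+' is dim-variable for it
# ("stain" downgrades the staining row).  Shared cells emit rows for
# both sexes unless listed in `male_only`.
_T2Row = tuple
_TABLE2_ROWS: list[dict] = [
    dict(label="tyramine + bas-1-depen-unknown monoamine?",
         levels="+--++----", stain=None, cells=["HOA"]),
    dict(label="tyramine + bas-1-depen-unknown monoamine?",
         levels="---++----", stain=None, cells=["R8A"]),
    dict(label="tyramine + dopamine",
         levels="+-+++----", stain="DA", cells=["R7A"]),
    dict(label="tyramine (+ uptake) + betaine (uptake)",
         levels="+---+--++", stain=None, cells=["RIM"]),
    dict(label="bas-1-depen-unknown monoamine?",
         levels="+--+-----", stain=None, cells=["R2A"]),
    dict(label="bas-1-depen-unknown monoamine?",
         levels="---+-----", stain=None,
         cells=["R3A", "R6A", "R6B*", "PCB", "SPC", "DVE", "DVF", "URB"],
         dim={"R6B": ["bas-1"]}),
    dict(label="octopamine", levels="+---++---", stain=None, cells=["RIC"]),
    dict(label="octopamine", levels="----++---", stain=None, cells=["R8B"]),
    dict(label="dopamine", levels="+-++-----", stain="DA",
         cells=["R5A", "R9A", "ADE", "CEP", "PDE"]),
    dict(label="5-HTP (synthesis) + 5-HT (alternative synthesis/uptake mechanism?)"
               " + unknown monoamine?",
         levels="-+---+---", stain="5-HT", cells=["CEM"]),
    dict(label="5-HTP", levels="-+-------", stain=None, cells=["MI"]),
    dict(label="PEOH?", levels="---+-+---", stain=None, cells=["R2B"]),
    dict(label="5-HT + PEOH?", levels="-+-+-+---", stain=None,
         cells=["R7B*"], dim={"R7B": ["tph-1"]}),
    dict(label="5-HT + PEOH?", levels="++-+-+---", stain="5-HT", cells=["R1B"]),
    dict(label="5-HT + PEOH?", levels="++-+-++--", stain="5-HT", cells=["R3B"]),
    dict(label="5-HT + PEOH?", levels="++-+-+---", stain=None,
         cells=["R4B*"], dim={"R4B": ["tph-1", "bas-1"]}),
    dict(label="5-HT (uptake)", levels="+-----+--", stain="5-HT",
         cells=["PGA", "RIH"]),
    dict(label="5-HT (uptake)", levels="------+--", stain="5-HT", cells=["AIM"]),
    dict(label="5-HT (uptake) + betaine (uptake)", levels="------++-",
         stain="5-HT", cells=["URX*"], dim={"URX": ["mod-5", "snf-3", "stain"]}),
    dict(label="5-HT (& uptake)", levels="++-+--+--", stain="5-HT",
         cells=["CP1-6", "ADF"]),
    dict(label="5-HT (alternative synthesis/uptake mechanism?)",
         levels=".........", stain="5-HT", cells=["I5*", "PVW"],
         dim={"I5": ["stain"]}, male_only={"PVW"}),
    dict(label="5-HT", levels="++-+-----", stain="5-HT", cells=["HSN"]),
    dict(label="5-HTP (synthesis) and 5-HT (uptake)",
         levels="++---++--", stain="5-HT", cells=["R9B"]),
    dict(label="5-HTP (synthesis) and 5-HT (alternative synthesis/uptake mechanism?)",
         levels="++-------", stain="5-HT", cells=["VC4-5*"],
         dim={"VC4": ["tph-1"], "VC5": ["tph-1"]}),
    dict(label="unknown monoamine?", levels="+........", stain=None,
         cells=["PVX", "PVY", "AVL*"], dim={"AVL": ["cat-1"]}),
    dict(label="unknown monoamine?", levels="-----+---", stain=None,
         cells=["HOB", "R5B", "IL2"]),
    dict(label="5-HT + betaine (uptake)", levels="++-+---+-", stain="5-HT",
         cells=["NSM*"], dim={"NSM": ["snf-3"]}),
    dict(label="betaine (uptake)", levels="+------+-", stain=None,
         cells=["PDC", "AUA", "CAN", "RIR*", "ASI*"],
         dim={"RIR": ["snf-3"], "ASI": ["snf-3"]}),
    dict(label="betaine (uptake)", levels="-------+-", stain=None,
         cells=["PHD", "PVV*", "M3*", "AIB", "DVB*", "SMD*", "RIS", "PDA*",
                "ASG*", "DA9*", "PHC", "PVN", "VA12*", "VB1-11*", "RMH*"],
         dim={c: ["snf-3"] for c in
              ["PVV", "M3", "DVB", "SMD", "PDA", "ASG", "DA9", "RMH"]
              + [f"VA12"] + [f"VB{i}" for i in range(1, 12)]}),
]


def _iter_table2(kb: KnowledgeBase):
    for row in _TABLE2_ROWS:
        dim_map = row.get("dim", {})
        male_only = row.get("male_only", set())
        for token in row["cells"]:
            starred = token.endswith("*")
            for cell in _expand([token.rstrip("*")]):
                yield row, cell, starred, dim_map.get(cell, []), cell in male_only


def fixture_table2(kb: KnowledgeBase | None = None) -> EvidenceTable:
    """Evidence encoding of the printed monoamine category table."""
    kb = kb or default_kb()
    obs: list[ExpressionObservation] = []
    seen = set()
    for row, cell, _starred, dim_genes, male_only in _iter_table2(kb):
        sexes = _sexes_for(kb, cell, male_only)
        for sex in sexes:
            for gene, mark in zip(TABLE2_GENES, row["levels"]):
                if mark == ".":
                    continue
                level = "present" if mark == "+" else "absent"
                if gene in dim_genes and level == "present":
                    level = "variable_dim"
                key = (gene, cell, sex)
                if key in seen:
                    continue
                seen.add(key)
                obs.append(ExpressionObservation(
                    gene, cell, sex, "reporter_allele", level,
                    provenance="category table"))
            if row["stain"] is not None:
                level = "variable_dim" if "stain" in dim_genes else "present"
                key = (row["stain"], cell, sex)
                if key in seen:
                    continue
                seen.add(key)
                obs.append(ExpressionObservation(
                    row["stain"], cell, sex, "direct_stain", level,
                    provenance="category table, direct staining"))
    return EvidenceTable(obs, kb=kb)


def table2_expectations(kb: KnowledgeBase | None = None):
    """Per-cell expected printed labels: (cell, sex, printed_label, starred)."""
    kb = kb or default_kb()
    out = []
    for row, cell, starred, _dim, male_only in _iter_table2(kb):
        for sex in _sexes_for(kb, cell, male_only):
            out.append((cell, sex, row["label"], starred))
    return out


# ---------------------------------------------------------------------
# Uptake table: neurons that uptake monoaminergic transmitters.
#
# Section tuples: (cell, male_only, {gene: mark}, stain_mark) where the
# mark is '+', '-', or '~' (printed "+/−").  All serotonin-section rows
# sit under the "anti-5-HT staining (+)" header; '~' on the stain means
# staining reported as variable.
_T1_SEROTONIN = [
    ("ADF", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("AIM", False, {"cat-1": "-", "mod-5": "+", "tph-1": "-"}, "+"),
    ("I5", False, {"cat-1": "~", "mod-5": "-", "tph-1": "-"}, "~"),
    ("NSM", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("PVW", True, {"cat-1": "-", "mod-5": "-", "tph-1": "-"}, "+"),
    ("RIH", False, {"cat-1": "+", "mod-5": "+", "tph-1": "-"}, "+"),
    ("URX", False, {"cat-1": "-", "mod-5": "~", "tph-1": "-"}, "~"),
    ("HSN", False, {"cat-1": "+", "mod-5": "-", "tph-1": "+"}, "+"),
    ("VC4", False, {"cat-1": "+", "mod-5": "-", "tph-1": "~"}, "~"),
    ("VC5", False, {"cat-1": "+", "mod-5": "-", "tph-1": "~"}, "~"),
    ("CEM", False, {"cat-1": "-", "mod-5": "+", "tph-1": "+"}, "~"),
    ("CP1", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("CP2", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("CP3", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("CP4", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("CP5", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("CP6", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("PGA", False, {"cat-1": "+", "mod-5": "+", "tph-1": "-"}, "+"),
    ("R1B", False, {"cat-1": "+", "mod-5": "-", "tph-1": "+"}, "+"),
    ("R3B", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
    ("R9B", False, {"cat-1": "+", "mod-5": "+", "tph-1": "+"}, "+"),
]

_T1_TYRAMINE = [("RIM", {"cat-1": "+", "oct-1": "+"})]

_T1_BETAINE = [
    ("AUA", "+", "+"), ("CAN", "+", "+"), ("NSM", "+", "~"), ("RIM", "+", "+"),
    ("RIR", "+", "~"), ("ASI", "+", "~"), ("M3", "-", "~"), ("AIB", "-", "+"),
    ("DVB", "-", "~"), ("SMD", "-", "~"), ("RIS", "-", "+"), ("URX", "-", "~"),
    ("PDA", "-", "~"), ("ASG", "-", "~"), ("DA9", "-", "~"),
    ("VB1", "-", "~"), ("VB2", "-", "~"), ("VB3", "-", "~"), ("VB4", "-", "~"),
    ("VB5", "-", "~"), ("VB6", "-", "~"), ("VB7", "-", "~"), ("VB8", "-", "~"),
    ("VB9", "-", "~"), ("VB10", "-", "~"), ("VB11", "-", "~"),
    ("PHC", "-", "+"), ("PVN", "-", "+"), ("VA12", "-", "~"), ("RMH", "-", "~"),
    ("PDC", "+", "+"), ("PHD", "-", "+"), ("PVV", "-", "~"),
]

_MARK_LEVEL = {"+": "present", "-": "absent", "~": "variable_dim"}


def fixture_table1(kb: KnowledgeBase | None = None) -> EvidenceTable:
    """Evidence encoding of the printed monoamine uptake table.

    One context row (RIM tdc-1, from the category table) accompanies the
    tyramine section, whose printed columns presuppose RIM's tyramine
    synthesis.
    """
    kb = kb or default_kb()
    obs: dict[tuple, ExpressionObservation] = {}

    def put(gene, cell, sex, modality, level, prov):
        key = (gene, cell, sex, modality)
        if key not in obs:
            obs[key] = ExpressionObservation(gene, cell, sex, modality, level,
                                             provenance=prov)

    def sex_of(cell, male_only=False):
        sexes = _sexes_for(kb, cell, male_only)
        # The uptake table is hermaphrodite-centric; shared cells carry one row.
        return "hermaphrodite" if "hermaphrodite" in sexes else "male"

    for cell, male_only, genes, stain in _T1_SEROTONIN:
        sex = sex_of(cell, male_only)
        for gene, mark in genes.items():
            put(gene, cell, sex, "reporter_allele", _MARK_LEVEL[mark],
                "uptake table, serotonin section")
        put("5-HT", cell, sex, "antibody_stain", _MARK_LEVEL[stain],
            "uptake table, anti-5-HT staining")
    for cell, genes in _T1_TYRAMINE:
        sex = sex_of(cell)
        for gene, mark in genes.items():
            put(gene, cell, sex, "reporter_allele", _MARK_LEVEL[mark],
                "uptake table, tyramine section")
        put("tdc-1", cell, sex, "reporter_allele", "present",
            "tyramine synthesis context (category table)")
    for cell, cat1, snf3 in _T1_BETAINE:
        sex = sex_of(cell)
        put("cat-1", cell, sex, "reporter_allele", _MARK_LEVEL[cat1],
            "uptake table, betaine section")
        put("snf-3", cell, sex, "reporter_allele", _MARK_LEVEL[snf3],
            "uptake table, betaine section")
    return EvidenceTable(list(obs.values()), kb=kb)


# ---------------------------------------------------------------------
# Male ventral-cord CA/CP per-neuron profiles.
#
# Per neuron: {gene-or-stain: level}; genes not listed were not called
# expressed in the caption ("no X" statements get explicit absent rows).
_FIG10C: dict[str, dict[str, str]] = {}
for _c in ["CA1", "CA2", "CA3", "CA4"]:
    _FIG10C[_c] = {"unc-17": "present", "unc-47": "present", "eat-4": "variable_dim"}
for _c in ["CA5", "CA6", "CA8"]:
    _FIG10C[_c] = {"unc-17": "present", "unc-47": "present"}
_FIG10C["CA7"] = {"unc-17": "present", "eat-4": "present", "unc-47": "absent"}
_FIG10C["CA9"] = {"unc-17": "variable_dim", "unc-47": "absent"}
_FIG10C["CP0"] = {"eat-4": "variable_dim"}
for _c in ["CP1", "CP2", "CP3", "CP4"]:
    _FIG10C[_c] = {"unc-17": "present", "unc-47": "present", "cat-1": "present",
                   "tph-1": "present", "bas-1": "present", "5-HT": "present"}
for _c in ["CP5", "CP6"]:
    _FIG10C[_c] = {"eat-4": "present", "unc-47": "present", "cat-1": "present",
                   "tph-1": "present", "bas-1": "present", "5-HT": "present"}
for _c in ["CP7", "CP8"]:
    _FIG10C[_c] = {"unc-17": "variable_dim", "unc-47": "variable_dim"}
_FIG10C["CP9"] = {"unc-25": "present", "unc-47": "present", "GABA": "present"}


def fixture_fig10c(kb: KnowledgeBase | None = None) -> EvidenceTable:
    """Per-neuron CA/CP profiles of the male ventral cord."""
    kb = kb or default_kb()
    obs = []
    for cell in sorted(_FIG10C):
        for gene, level in _FIG10C[cell].items():
            modality = "antibody_stain" if gene in ("5-HT", "GABA") else "reporter_allele"
            obs.append(ExpressionObservation(
                gene, cell, "male", modality, level,
                provenance="male ventral-cord profile figure"))
    return EvidenceTable(obs, kb=kb)
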
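"""Neurotransmitter pathway and cell-ontology knowledge base.

The knowledge base bundles four things that every other stage of the
pipeline resolves against:

* the neurotransmitter **pathway genes** (vesicular transporters,
  biosynthetic enzymes, plasma-membrane uptake transporters, plus the
  UNC-46/LAMP sorting co-factor),
* the **pathway steps** (enzyme, substrate, product) of monoamine and
  GABA biosynthesis,
* the **transmitters** themselves, each mapped to the vesicular
  transporter whose expression is the release criterion,
* the **cell ontology** of both sexes: every neuron class with its
  member count, plus the glia and non-neuronal cell types that carry
  pathway-gene expression.

The shipped default covers the 302 neurons (118 classes) of the adult
hermaphrodite and the 93 male-specific neurons.  The male census is not
printed in any single table of the primary literature; it follows the
adult male wiring-diagram census and is deliberately kept in the YAML
config so it can be swapped without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

__all__ = [
    "PathwayGene",
    "PathwayStep",
    "Transmitter",
    "CellClass",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "default_kb",
    "synthesis_requirements",
    "GENE_ROLES",
    "CELL_KINDS",
    "SEX_SCOPES",
    "SEXES",
]

GENE_ROLES = frozenset(
    {"vesicular_transporter", "synthesis_enzyme", "uptake_transporter", "sorting_cofactor"}
)
CELL_KINDS = frozenset({"neuron", "glia", "non_neuronal"})
SEX_SCOPES = frozenset({"shared", "male_specific", "hermaphrodite_specific"})
SEXES = ("hermaphrodite", "male")

#: The sixteen loci in scope.  snf-11 enters only as a prior-literature
#: GABA-uptake evidence channel (no new reporter was generated for it).
IN_SCOPE_LOCI = frozenset(
    {
        "eat-4", "unc-17", "unc-25", "unc-46", "unc-47",
        "tph-1", "bas-1", "cat-2", "tdc-1", "tbh-1",
        "cat-1", "hdl-1", "mod-5", "snf-3", "oct-1", "snf-11",
    }
)

#: Antibody / direct staining targets usable in the ``gene`` column of
#: evidence rows when the modality is a staining modality.
STAIN_TARGETS = frozenset({"5-HT", "GABA", "DA"})


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge base violates its schema or invariants."""


@dataclass(frozen=True)
class PathwayGene:
    symbol: str
    role: str
    orthology_note: str = ""

    def __post_init__(self) -> None:
        if self.role not in GENE_ROLES:
            raise KnowledgeBaseError(f"unknown gene role {self.role!r} for {self.symbol}")


@dataclass(frozen=True)
class PathwayStep:
    enzyme: str
    substrate: str
    product: str


@dataclass(frozen=True)
class Transmitter:
    name: str
    vesicular_transporter: str | None = None


@dataclass(frozen=True)
class CellClass:
    name: str
    kind: str
    sex_scope: str
    members_per_sex: int
    member_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in CELL_KINDS:
            raise KnowledgeBaseError(f"unknown cell kind {self.kind!r} for {self.name}")
        if self.sex_scope not in SEX_SCOPES:
            raise KnowledgeBaseError(f"unknown sex scope {self.sex_scope!r} for {self.name}")
        if self.members_per_sex < 1:
            raise KnowledgeBaseError(f"class {self.name} must have >= 1 member")
        if self.member_names is not None and len(self.member_names) != self.members_per_sex:
            raise KnowledgeBaseError(
                f"class {self.name}: {len(self.member_names)} member names for "
                f"{self.members_per_sex} members"
            )

    def present_in(self, sex: str) -> bool:
        if self.sex_scope == "shared":
            return True
        return (self.sex_scope == "male_specific") == (sex == "male")


@dataclass
class KnowledgeBase:
    """Validated, resolvable container for genes, steps, transmitters and cells."""

    genes: dict[str, PathwayGene]
    steps: list[PathwayStep]
    transmitters: dict[str, Transmitter]
    cell_classes: dict[str, CellClass]
    version: str = "1"
    census_source: str = ""
    _member_index: dict[str, tuple[str, str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self._member_index = {}
        for cls in self.cell_classes.values():
            for member in cls.member_names or ():
                if member in self.cell_classes or member in self._member_index:
                    raise KnowledgeBaseError(f"ambiguous cell name {member!r}")
                self._member_index[member] = (cls.name, member)

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        if set(self.genes) != IN_SCOPE_LOCI:
            missing = IN_SCOPE_LOCI - set(self.genes)
            extra = set(self.genes) - IN_SCOPE_LOCI
            raise KnowledgeBaseError(
                f"gene set mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        for step in self.steps:
            if step.enzyme not in self.genes:
                raise KnowledgeBaseError(f"unknown gene symbol {step.enzyme!r} in pathway step")
        for t in self.transmitters.values():
            if t.vesicular_transporter is not None and t.vesicular_transporter not in self.genes:
                raise KnowledgeBaseError(
                    f"transmitter {t.name}: unknown vesicular transporter "
                    f"{t.vesicular_transporter!r}"
                )
        # Metabolite graph must be acyclic (a biosynthetic cascade).
        g = nx.DiGraph()
        for step in self.steps:
            g.add_edge(step.substrate, step.product, enzyme=step.enzyme)
        if not nx.is_directed_acyclic_graph(g):
            raise KnowledgeBaseError("pathway metabolite graph contains a cycle")

    # -- cell resolution ----------------------------------------------

    def resolve_cell(self, name: str) -> tuple[CellClass, str | None]:
        """Resolve a cell name to ``(class, member-or-None)``.

        Accepts either a class name (``"AIM"``, ``"R9B"``) or an
        individually named class member (``"VC4"``, ``"CP0"``,
        ``"AS10"``).
        """
        if name in self.cell_classes:
            return self.cell_classes[name], None
        if name in self._member_index:
            cls_name, member = self._member_index[name]
            return self.cell_classes[cls_name], member
        raise KeyError(name)

    def neuron_classes(self, sex: str) -> list[CellClass]:
        return [
            c
            for c in self.cell_classes.values()
            if c.kind == "neuron" and c.present_in(sex)
        ]

    def neuron_total(self, sex: str) -> int:
        return sum(c.members_per_sex for c in self.neuron_classes(sex))

    def male_specific_neuron_total(self) -> int:
        return sum(
            c.members_per_sex
            for c in self.cell_classes.values()
            if c.kind == "neuron" and c.sex_scope == "male_specific"
        )

    # -- serialization ------------------------------------------------

    def to_mapping(self) -> dict:
        doc: dict = {
            "schema_version": self.version,
            "census_source": self.census_source,
            "genes": [
                {"symbol": g.symbol, "role": g.role, "orthology_note": g.orthology_note}
                for g in sorted(self.genes.values(), key=lambda g: g.symbol)
            ],
            "steps": [
                {"enzyme": s.enzyme, "substrate": s.substrate, "product": s.product}
                for s in self.steps
            ],
            "transmitters": [
                {"name": t.name, "vesicular_transporter": t.vesicular_transporter}
                for t in self.transmitters.values()
            ],
            "cell_classes": [],
        }
        for c in sorted(self.cell_classes.values(), key=lambda c: c.name):
            entry: dict = {
                "name": c.name,
                "kind": c.kind,
                "sex_scope": c.sex_scope,
                "members_per_sex": c.members_per_sex,
            }
            if c.member_names is not None:
                entry["member_names"] = list(c.member_names)
            doc["cell_classes"].append(entry)
        return doc

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=False, allow_unicode=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.serialize(), encoding="utf-8")


def _build(doc: Mapping) -> KnowledgeBase:
    try:
        genes = {
            g["symbol"]: PathwayGene(g["symbol"], g["role"], g.get("orthology_note", ""))
            for g in doc["genes"]
        }
        steps = [PathwayStep(s["enzyme"], s["substrate"], s["product"]) for s in doc["steps"]]
        transmitters = {
            t["name"]: Transmitter(t["name"], t.get("vesicular_transporter"))
            for t in doc["transmitters"]
        }
        cells: dict[str, CellClass] = {}
        for c in doc["cell_classes"]:
            if c["name"] in cells:
                raise KnowledgeBaseError(f"duplicate cell class name {c['name']!r}")
            member_names = c.get("member_names")
            cells[c["name"]] = CellClass(
                c["name"],
                c["kind"],
                c["sex_scope"],
                c["members_per_sex"],
                tuple(member_names) if member_names else None,
            )
    except KeyError as exc:  # missing schema field
        raise KnowledgeBaseError(f"knowledge base document missing field {exc}") from exc
    return KnowledgeBase(
        genes=genes,
        steps=steps,
        transmitters=transmitters,
        cell_classes=cells,
        version=str(doc.get("schema_version", "1")),
        census_source=doc.get("census_source", ""),
    )


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from its YAML config."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _build(doc)


_DEFAULT_PATH = Path(__file__).parent / "data" / "knowledge_base.yaml"
_default_cache: KnowledgeBase | None = None


def default_kb() -> KnowledgeBase:
    """The shipped default knowledge base (loaded once, then cached)."""
    global _default_cache
    if _default_cache is None:
        _default_cache = load_knowledge_base(_DEFAULT_PATH)
    return _default_cache


# -- synthesis requirements -------------------------------------------

#: Minimal enzyme sets sufficient for synthesis of each canonical
#: transmitter.  ACh synthesis (cha-1/ChAT) shares an operon with
#: unc-17/VAChT and is treated as implied by it; glutamate is a
#: metabolic intermediate requiring no dedicated enzyme.  Betaine has no
#: enzymatic route inside the nervous-system KB (synthesis in RIM is a
#: KB annotation, uptake via snf-3 is the operative evidence).
_SYNTHESIS: dict[str, frozenset[frozenset[str]]] = {
    "5-HT": frozenset({frozenset({"tph-1", "bas-1"})}),
    "DA": frozenset({frozenset({"cat-2", "bas-1"})}),
    "TA": frozenset({frozenset({"tdc-1"})}),
    "OA": frozenset({frozenset({"tdc-1", "tbh-1"})}),
    "GABA": frozenset({frozenset({"unc-25"})}),
    "ACh": frozenset({frozenset()}),
    "Glu": frozenset({frozenset()}),
    "5-HTP": frozenset({frozenset({"tph-1"})}),
    "betaine": frozenset(),
}


def synthesis_requirements(transmitter: str | Transmitter) -> frozenset[frozenset[str]]:
    """Gene combinations sufficient for synthesis of a canonical transmitter.

    Returns a set of alternative gene sets; an empty *inner* set means
    synthesis is implied (ACh, Glu), an empty *outer* set means no
    enzymatic route exists in the KB (betaine).  Unknown-class
    transmitters raise ``KeyError``.
    """
    name = transmitter.name if isinstance(transmitter, Transmitter) else transmitter
    if name not in _SYNTHESIS:
        raise KeyError(f"no synthesis requirements defined for transmitter {name!r}")
    return _SYNTHESIS[name]


def synthesis_enzymes() -> frozenset[str]:
    """All enzymes named by any synthesis requirement."""
    return frozenset(g for combos in _SYNTHESIS.values() for combo in combos for g in combo)


def iter_census(kb: KnowledgeBase, sex: str, kind: str = "neuron") -> Iterable[CellClass]:
    return (c for c in kb.cell_classes.values() if c.kind == kind and c.present_in(sex))
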
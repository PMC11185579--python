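"""Knowledge-base schema, census totals and pathway structure."""

import networkx as nx
import pytest
import yaml

from ntatlas.knowledge import (
    KnowledgeBaseError,
    load_knowledge_base,
    synthesis_requirements,
    _DEFAULT_PATH,
)


def test_census_totals(kb):
    assert kb.neuron_total("hermaphrodite") == 302
    assert kb.male_specific_neuron_total() == 93
    # male total = shared neurons + male-specific
    herm_specific = sum(
        c.members_per_sex for c in kb.cell_classes.values()
        if c.kind == "neuron" and c.sex_scope == "hermaphrodite_specific"
    )
    assert kb.neuron_total("male") == 302 - herm_specific + 93


def test_sixteen_loci_and_roles(kb):
    assert len(kb.genes) == 16
    vesicular = {s for s, g in kb.genes.items() if g.role == "vesicular_transporter"}
    assert vesicular == {"eat-4", "unc-17", "unc-47", "cat-1"}
    uptake = {s for s, g in kb.genes.items() if g.role == "uptake_transporter"}
    assert uptake == {"mod-5", "snf-3", "oct-1", "snf-11"}


def test_transmitter_transporter_mapping(kb):
    assert kb.transmitters["ACh"].vesicular_transporter == "unc-17"
    assert kb.transmitters["Glu"].vesicular_transporter == "eat-4"
    assert kb.transmitters["GABA"].vesicular_transporter == "unc-47"
    for name in ("5-HT", "DA", "TA", "OA", "betaine"):
        assert kb.transmitters[name].vesicular_transporter == "cat-1"
    assert kb.transmitters["unknown_VGAT_substrate"].vesicular_transporter == "unc-47"
    assert kb.transmitters["unknown_MA"].vesicular_transporter == "cat-1"
    assert kb.transmitters["5-HTP"].vesicular_transporter is None


@pytest.mark.parametrize(
    "transmitter, expected",
    [
        ("5-HT", {frozenset({"tph-1", "bas-1"})}),
        ("DA", {frozenset({"cat-2", "bas-1"})}),
        ("TA", {frozenset({"tdc-1"})}),
        ("OA", {frozenset({"tdc-1", "tbh-1"})}),
        ("GABA", {frozenset({"unc-25"})}),
        ("ACh", {frozenset()}),
        ("Glu", {frozenset()}),
        ("5-HTP", {frozenset({"tph-1"})}),
        ("betaine", set()),
    ],
)
def test_synthesis_requirements(transmitter, expected):
    assert synthesis_requirements(transmitter) == frozenset(expected)


def test_synthesis_requirements_unknown_transmitter_rejected():
    with pytest.raises(KeyError):
        synthesis_requirements("unknown_MA")


def test_every_required_enzyme_is_a_pathway_step_enzyme(kb):
    step_enzymes = {s.enzyme for s in kb.steps}
    for t in ("5-HT", "DA", "TA", "OA", "GABA", "5-HTP"):
        for combo in synthesis_requirements(t):
            assert combo <= step_enzymes


def test_pathway_steps_match_biosynthesis(kb):
    triples = {(s.enzyme, s.substrate, s.product) for s in kb.steps}
    assert ("tph-1", "tryptophan", "5-HTP") in triples
    assert ("bas-1", "5-HTP", "5-HT") in triples
    assert ("bas-1", "L-Dopa", "DA") in triples
    assert ("cat-2", "tyrosine", "L-Dopa") in triples
    assert ("tdc-1", "tyrosine", "TA") in triples
    assert ("tbh-1", "TA", "OA") in triples
    assert ("unc-25", "glutamate", "GABA") in triples


def test_metabolite_graph_is_dag(kb):
    g = nx.DiGraph((s.substrate, s.product) for s in kb.steps)
    assert nx.is_directed_acyclic_graph(g)
    assert list(nx.topological_sort(g))


def test_roundtrip_serialization_is_byte_identical(kb):
    shipped = _DEFAULT_PATH.read_text(encoding="utf-8")
    assert kb.serialize() == shipped


def test_member_name_resolution(kb):
    cls, member = kb.resolve_cell("VC4")
    assert cls.name == "VC" and member == "VC4"
    cls, member = kb.resolve_cell("CP0")
    assert cls.name == "CP" and member == "CP0"
    cls, member = kb.resolve_cell("AIM")
    assert cls.name == "AIM" and member is None
    with pytest.raises(KeyError):
        kb.resolve_cell("FAKE")


def test_unknown_step_gene_rejected(tmp_path, kb):
    doc = yaml.safe_load(kb.serialize())
    doc["steps"].append({"enzyme": "xyz-1", "substrate": "a", "product": "b"})
    path = tmp_path / "kb.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    with pytest.raises(KnowledgeBaseError, match="xyz-1"):
        load_knowledge_base(path)


def test_duplicate_class_name_rejected(tmp_path, kb):
    doc = yaml.safe_load(kb.serialize())
    doc["cell_classes"].append(dict(doc["cell_classes"][0]))
    path = tmp_path / "kb.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    with pytest.raises(KnowledgeBaseError, match="duplicate"):
        load_knowledge_base(path)
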
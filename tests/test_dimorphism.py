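"""Sexual dimorphism detection on shared classes."""

from ntatlas.consensus import reconcile
from ntatlas.dimorphism import detect_dimorphisms
from ntatlas.evidence import EvidenceTable, ExpressionObservation
from ntatlas.reconstruction import DIMORPHIC_UNC47
from ntatlas.rules import assign_transmitters


def _split(calls):
    return ([c for c in calls if c.sex == "hermaphrodite"],
            [c for c in calls if c.sex == "male"])


def _records(ev, kb):
    calls_h, calls_m = _split(reconcile(ev, kb))
    return detect_dimorphisms(
        calls_h, calls_m,
        assign_transmitters(calls_h, kb), assign_transmitters(calls_m, kb), kb)


def test_identical_calls_give_empty_set(kb):
    rows = [
        ExpressionObservation("eat-4", "AIB", sex, "reporter_allele", "present")
        for sex in ("hermaphrodite", "male")
    ]
    assert _records(EvidenceTable(rows, kb=kb), kb) == set()


def test_on_off_and_symmetry(kb):
    rows = [ExpressionObservation("unc-47", "ADF", "male", "reporter_allele",
                                  "present")]
    ev = EvidenceTable(rows, kb=kb)
    calls_h, calls_m = _split(reconcile(ev, kb))
    fwd = detect_dimorphisms(calls_h, calls_m, [], [], kb)
    assert {(r.cell, r.type, r.higher_sex) for r in fwd} == {("ADF", "on_off", "male")}
    # swapping the sexes flips higher_sex and nothing else
    from dataclasses import replace

    swapped = detect_dimorphisms(
        [replace(c, sex="hermaphrodite") for c in calls_m],
        [replace(c, sex="male") for c in calls_h],
        [], [], kb)
    assert {(r.cell, r.feature, r.type) for r in swapped} == {
        (r.cell, r.feature, r.type) for r in fwd}
    assert {r.higher_sex for r in swapped} == {"hermaphrodite"}


def test_scaling_requires_intensity_annotation(kb):
    with_intensity = [
        ExpressionObservation("eat-4", "PVN", "hermaphrodite", "reporter_allele",
                              "variable_dim", intensity="low"),
        ExpressionObservation("eat-4", "PVN", "male", "reporter_allele",
                              "present", intensity="high"),
    ]
    recs = _records(EvidenceTable(with_intensity, kb=kb), kb)
    assert {(r.cell, r.feature, r.type, r.higher_sex) for r in recs} == {
        ("PVN", "eat-4", "scaling", "male")}
    # without the annotation only on_off/switch are emitted
    without = [
        ExpressionObservation("eat-4", "PVN", "hermaphrodite", "reporter_allele",
                              "variable_dim"),
        ExpressionObservation("eat-4", "PVN", "male", "reporter_allele", "present"),
    ]
    assert _records(EvidenceTable(without, kb=kb), kb) == set()


def test_atlas_reconstruction_dimorphisms(kb, atlas_ev):
    recs = _records(atlas_ev, kb)
    unc47_on_off = {
        r.cell for r in recs if r.feature == "unc-47" and r.type == "on_off"
    }
    assert unc47_on_off == set(DIMORPHIC_UNC47)
    assert all(
        r.higher_sex == "male"
        for r in recs if r.feature == "unc-47" and r.type == "on_off"
    )
    # AIM switches from glutamatergic to cholinergic in adult males
    aim = {r.type for r in recs if r.cell == "AIM"}
    assert "switch" in aim
    # mod-5 in ADF is higher in hermaphrodites; eat-4 in PVN higher in males
    assert any(r.cell == "ADF" and r.feature == "mod-5" and r.type == "scaling"
               and r.higher_sex == "hermaphrodite" for r in recs)
    assert any(r.cell == "PVN" and r.feature == "eat-4" and r.type == "scaling"
               and r.higher_sex == "male" for r in recs)
    # records are emitted for sex-shared classes only
    for r in recs:
        assert kb.resolve_cell(r.cell)[0].sex_scope == "shared"
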
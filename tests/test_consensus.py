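"""Consensus reconciliation: precedence, conflicts, invariances."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ntatlas.consensus import call_index, reconcile, stain_status
from ntatlas.evidence import EvidenceTable, ExpressionObservation, scrna_level


def _table(rows, kb=None):
    return EvidenceTable(list(rows), kb=kb, strict=False)


def obs(gene="cat-2", cell="OLL", sex="hermaphrodite", modality="reporter_allele",
        level="present", k=None):
    return ExpressionObservation(gene, cell, sex, modality, level,
                                 scrna_threshold_pass=k)


def test_reporter_absent_beats_dim_scrna_with_conflict():
    # scRNA transcripts at lower thresholds, but the knock-in reporter
    # shows nothing: the call is absent and the disagreement is flagged.
    calls = reconcile(_table([
        obs(modality="scrna", level="variable_dim", k=2),
        obs(modality="reporter_allele", level="absent"),
    ]))
    (c,) = calls
    assert c.level == "absent" and c.conflict


def test_concordant_reporter_and_scrna_present_without_conflict():
    calls = reconcile(_table([
        obs(gene="unc-17", cell="RIP", modality="scrna", level="present", k=4),
        obs(gene="unc-17", cell="RIP", modality="reporter_allele", level="present"),
    ]))
    (c,) = calls
    assert c.level == "present" and not c.conflict
    assert c.supporting_modalities == {"scrna", "reporter_allele"}


@pytest.mark.parametrize("k, expected", [
    (0, "absent"), (1, "variable_dim"), (2, "variable_dim"),
    (3, "variable_dim"), (4, "present"),
])
def test_scrna_alone_establishes_present_only_at_four_thresholds(k, expected):
    calls = reconcile(_table([
        obs(modality="scrna", level=scrna_level(k), k=k),
    ]))
    (c,) = calls
    assert c.level == expected


def test_reporter_beats_fosmid():
    calls = reconcile(_table([
        obs(modality="fosmid_reporter", level="present"),
        obs(modality="reporter_allele", level="absent"),
    ]))
    assert calls[0].level == "absent" and calls[0].conflict


def test_larval_rows_excluded():
    larval = ExpressionObservation(
        "tph-1", "pharyngeal_muscle", "hermaphrodite", "reporter_allele",
        "present", stage="larval")
    assert reconcile(_table([larval])) == []


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.randoms(use_true_random=False))
def test_permutation_invariance(rng):
    rows = [
        obs(gene=g, cell=c, modality=m, level=lv,
            k={"absent": 0, "variable_dim": 2, "present": 4}[lv] if m == "scrna" else None)
        for g in ("cat-1", "eat-4")
        for c in ("OLL", "RIM")
        for m, lv in [
            ("reporter_allele", rng.choice(["absent", "variable_dim", "present"])),
            ("fosmid_reporter", rng.choice(["absent", "present"])),
            ("scrna", rng.choice(["absent", "variable_dim", "present"])),
        ]
    ]
    shuffled = rows[:]
    rng.shuffle(shuffled)
    assert reconcile(_table(rows)) == reconcile(_table(shuffled))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.randoms(use_true_random=False))
def test_dropping_scrna_never_changes_reporter_decided_calls(rng):
    rows = [
        obs(gene="cat-1", cell=c, modality=m, level=lv,
            k=2 if m == "scrna" and lv == "variable_dim" else
              4 if m == "scrna" and lv == "present" else
              0 if m == "scrna" else None)
        for c in ("OLL", "RIM", "AIM")
        for m, lv in [
            ("reporter_allele", rng.choice(["absent", "variable_dim", "present"])),
            ("scrna", rng.choice(["absent", "variable_dim", "present"])),
        ]
    ]
    full = call_index(reconcile(_table(rows)))
    no_scrna = call_index(reconcile(_table(
        [r for r in rows if r.modality != "scrna"])))
    for key, call in no_scrna.items():
        assert full[key].level == call.level


def test_reconcile_is_idempotent_under_repetition(table2_ev, kb):
    once = reconcile(table2_ev, kb)
    again = reconcile(table2_ev, kb)
    assert once == again


def test_single_modality_fixture_degenerates_to_identity(table2_ev, kb):
    idx = call_index(reconcile(table2_ev, kb))
    for o in table2_ev:
        assert idx[(o.gene, o.cell, o.sex)].level == o.level


def test_stain_status_examples(kb, table1_ev, atlas_ev):
    assert stain_status(table1_ev, "AIM", "hermaphrodite", "5-HT") == "positive"
    assert stain_status(atlas_ev, "AVA", "hermaphrodite", "GABA") == "positive"
    assert stain_status(table1_ev, "RIM", "hermaphrodite", "5-HT") == "unknown"
    with pytest.raises(KeyError):
        stain_status(table1_ev, "RIM", "hermaphrodite", "ACh")
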
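"""Rule engine: example assignments, labels, partitions, invariants."""

import itertools

import numpy as np
import pytest

from _oracle import oracle_flags
from conftest import assignments_by_cell
from ntatlas.consensus import reconcile
from ntatlas.rules import (
    CLASSIFICATION_GENES,
    assign_profile,
    assign_transmitters,
    categorize,
    normalize_printed_label,
    subclass_partition,
)

LEVELS = ("absent", "variable_dim", "present")


def _flags(levels, stains=None):
    return frozenset(a.flags for a in assign_profile(levels, stains))


def by_transmitter(assignments):
    return {a.transmitter: a for a in assignments}


class TestExampleAssignments:
    def test_octopaminergic_with_release(self):
        # tdc-1 + tbh-1 + cat-1: synthesizes and vesicularly releases OA
        a = by_transmitter(assign_profile(
            {"tdc-1": "present", "tbh-1": "present", "cat-1": "present"}))["OA"]
        assert a.synthesizes and a.vesicular_release

    def test_octopamine_synthesis_without_vmat_cannot_release(self):
        a = by_transmitter(assign_profile(
            {"tdc-1": "present", "tbh-1": "present"}))["OA"]
        assert a.synthesizes and not a.vesicular_release

    def test_tph1_only_neuron_makes_5htp_without_release(self):
        assigns = by_transmitter(assign_profile({"tph-1": "present"}))
        assert set(assigns) == {"5-HTP"}
        assert assigns["5-HTP"].synthesizes
        assert not assigns["5-HTP"].vesicular_release

    def test_serotonin_clearance_neuron(self):
        # mod-5 uptake without cat-1: a 5-HT sink, not a signaler
        a = by_transmitter(assign_profile(
            {"mod-5": "present"}, {"5-HT": "present"}))["5-HT"]
        assert a.uptakes and not a.vesicular_release and not a.synthesizes

    def test_all_absent_profile_yields_no_assignments(self):
        assert assign_profile({}) == []

    def test_tyramine_requires_absent_tbh1(self):
        only_tdc = by_transmitter(assign_profile(
            {"tdc-1": "present", "cat-1": "present"}))
        assert "TA" in only_tdc and "OA" not in only_tdc
        with_tbh = by_transmitter(assign_profile(
            {"tdc-1": "present", "tbh-1": "present", "cat-1": "present"}))
        assert "OA" in with_tbh and "TA" not in with_tbh

    def test_gaba_stain_without_route_is_unconventional(self):
        # anti-GABA-positive but no GAD, no snf-11, no VGAT
        a = by_transmitter(assign_profile({}, {"GABA": "present"}))["GABA"]
        assert a.unconventional_acquisition and not a.uptakes

    def test_gaba_uptake_via_snf11(self):
        a = by_transmitter(assign_profile(
            {"snf-11": "present"}, {"GABA": "present"}))["GABA"]
        assert a.uptakes and not a.unconventional_acquisition

    def test_vgat_orphan_flagged_only_without_gaba_evidence(self):
        assigns = by_transmitter(assign_profile({"unc-47": "present"}))
        assert set(assigns) == {"unknown_VGAT_substrate"}
        assert assigns["unknown_VGAT_substrate"].vesicular_release
        with_stain = by_transmitter(assign_profile(
            {"unc-47": "present"}, {"GABA": "present"}))
        assert "unknown_VGAT_substrate" not in with_stain


class TestOracleEquivalence:
    def test_exhaustive_grid_over_classification_genes(self):
        """Engine matches the brute-force evaluator on all 3^10 profiles."""
        for combo in itertools.product(LEVELS, repeat=len(CLASSIFICATION_GENES)):
            levels = {
                g: lv for g, lv in zip(CLASSIFICATION_GENES, combo)
                if lv != "absent"
            }
            assert _flags(levels) == oracle_flags(levels), levels

    def test_random_grid_including_uptake_genes_and_stains(self):
        rng = np.random.default_rng(2024)
        genes = CLASSIFICATION_GENES + ("mod-5", "snf-3", "oct-1", "snf-11")
        stains = ("GABA", "5-HT", "DA")
        for _ in range(4000):
            levels = {
                g: LEVELS[k] for g, k in zip(genes, rng.integers(0, 3, len(genes)))
                if k
            }
            stain_levels = {
                s: LEVELS[k] for s, k in zip(stains, rng.integers(0, 3, len(stains)))
                if k
            }
            assert _flags(levels, stain_levels) == oracle_flags(levels, stain_levels)


class TestInvariants:
    def test_release_implies_transporter_expression(self):
        rng = np.random.default_rng(7)
        transporter_of = {"GABA": "unc-47", "Glu": "eat-4", "ACh": "unc-17",
                          "unknown_VGAT_substrate": "unc-47"}
        genes = CLASSIFICATION_GENES + ("mod-5", "snf-3", "oct-1", "snf-11")
        for _ in range(2000):
            levels = {
                g: LEVELS[k] for g, k in zip(genes, rng.integers(0, 3, len(genes)))
                if k
            }
            for a in assign_profile(levels):
                if not a.vesicular_release:
                    continue
                gene = transporter_of.get(a.transmitter, "cat-1")
                assert levels.get(gene, "absent") != "absent"

    def test_determinism_under_call_shuffling(self, table2_ev, kb):
        calls = reconcile(table2_ev, kb)
        rng = np.random.default_rng(0)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        assert assign_transmitters(calls, kb) == assign_transmitters(shuffled, kb)

    def test_never_both_oa_and_ta_synthesis(self):
        for combo in itertools.product(("absent", "present"), repeat=3):
            levels = {g: lv for g, lv in zip(("tdc-1", "tbh-1", "cat-1"), combo)}
            ts = by_transmitter(assign_profile(levels))
            assert not ("OA" in ts and "TA" in ts and ts["TA"].synthesizes)


class TestCategorize:
    @pytest.mark.parametrize(
        "levels, stains, expected",
        [
            ({"tdc-1": "present", "oct-1": "present", "cat-1": "present",
              "snf-3": "present"}, {},
             "tyramine (+ uptake) + betaine (uptake)"),
            ({"tdc-1": "present", "cat-2": "present", "bas-1": "present",
              "cat-1": "present"}, {"DA": "present"},
             "dopamine + tyramine"),
            ({"eat-4": "present", "unc-17": "present"}, {}, "Glu + ACh"),
        ],
    )
    def test_label_composition(self, kb, levels, stains, expected):
        label = categorize(assign_profile(levels, stains, cell="RIM", sex="male"), kb)
        assert label.label == expected

    def test_orphan_label_for_bare_neuron(self, kb):
        assert categorize([], kb, cell="PVQ").label == "orphan/neuropeptidergic"

    def test_non_neuronal_cells_labeled_by_kind(self, kb):
        assert categorize([], kb, cell="AMsh").label == "none (glia)"

    def test_dim_supporting_gene_appends_star(self, kb):
        label = categorize(
            assign_profile({"cat-1": "variable_dim"}, cell="AVL"), kb)
        assert label.label == "unknown monoamine?*"

    def test_printed_label_normalization_reorders_and_rewrites(self):
        assert (
            normalize_printed_label("5-HTP (synthesis) and 5-HT (uptake)")
            == "5-HTP + 5-HT (uptake)"
        )
        assert normalize_printed_label("tyramine + dopamine") == "dopamine + tyramine"
        assert normalize_printed_label("octopamine", starred=True) == "octopamine*"


class TestSubclassPartition:
    def test_uniform_profiles_collapse_to_one_group(self, kb):
        from ntatlas.evidence import EvidenceTable, ExpressionObservation

        rows = [
            ExpressionObservation("unc-17", f"CA{i}", "male", "reporter_allele",
                                  "present")
            for i in range(1, 10)
        ]
        groups = subclass_partition(EvidenceTable(rows, kb=kb), "CA", kb)
        assert len(groups) == 1 and len(groups[0][1]) == 9

    def test_fig10c_groups(self, kb, fig10c_ev):
        ca = subclass_partition(fig10c_ev, "CA", kb)
        cp = subclass_partition(fig10c_ev, "CP", kb)
        assert sorted(map(len, (g for _, g in ca))) == [1, 1, 3, 4]
        assert sorted(map(len, (g for _, g in cp))) == [1, 1, 2, 2, 4]
        # the four-member group is CA1-CA4 / CP1-CP4
        assert ["CA1", "CA2", "CA3", "CA4"] in [g for _, g in ca]
        assert ["CP1", "CP2", "CP3", "CP4"] in [g for _, g in cp]


def test_cotransmitting_cp_neurons_release_at_least_two(kb, fig10c_ev):
    calls = reconcile(fig10c_ev, kb)
    by_cell = assignments_by_cell(assign_transmitters(calls, kb))
    released = {
        a.transmitter for a in by_cell[("CP1", "male")] if a.vesicular_release
    }
    assert "ACh" in released and "5-HT" in released
    assert len(released) >= 2
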
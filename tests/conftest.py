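import pytest

from ntatlas.consensus import reconcile
from ntatlas.fixtures import fixture_fig10c, fixture_table1, fixture_table2
from ntatlas.knowledge import default_kb
from ntatlas.reconstruction import full_atlas_evidence, s1_concordance_evidence
from ntatlas.rules import assign_transmitters


@pytest.fixture(scope="session")
def kb():
    return default_kb()


@pytest.fixture(scope="session")
def table1_ev(kb):
    return fixture_table1(kb)


@pytest.fixture(scope="session")
def table2_ev(kb):
    return fixture_table2(kb)


@pytest.fixture(scope="session")
def fig10c_ev(kb):
    return fixture_fig10c(kb)


@pytest.fixture(scope="session")
def atlas_ev(kb):
    return full_atlas_evidence(kb)


@pytest.fixture(scope="session")
def atlas_calls(atlas_ev, kb):
    return reconcile(atlas_ev, kb)


@pytest.fixture(scope="session")
def atlas_assignments(atlas_calls, kb):
    return assign_transmitters(atlas_calls, kb)


@pytest.fixture(scope="session")
def s1_ev(kb):
    return s1_concordance_evidence(kb)


def assignments_by_cell(assignments):
    out = {}
    for a in assignments:
        out.setdefault((a.cell, a.sex), []).append(a)
    return out
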
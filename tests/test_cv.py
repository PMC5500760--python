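"""Controlled-vocabulary engine: OBO loading, hierarchy queries, round trip."""

import io

import pytest

from mzidkit import cv as cvmod
from mzidkit.errors import CvLookupError, CvStructureError, OboParseError
from mzidkit.terms import WORKFLOW_FLAGS

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: MS:1
name: root

[Term]
id: MS:2
name: mid
is_a: MS:1 ! root

[Term]
id: MS:3
name: leaf
is_a: MS:2 ! mid
"""


@pytest.fixture(scope="module")
def subset():
    return cvmod.load_psi_ms_subset()


def test_vendored_subset_resolves_every_workflow_flag(subset):
    for acc in WORKFLOW_FLAGS:
        assert acc in subset
    assert subset.name_of("MS:1002490") == "peptide-level scoring"
    assert subset.name_of("MS:1002494") == "cross-linking search"


def test_empty_stream_gives_empty_graph():
    assert len(cvmod.load_cv("")) == 0


def test_closure_walks_the_is_a_chain():
    graph = cvmod.load_cv(CHAIN_OBO)
    assert graph.closure("MS:3") == {"MS:3", "MS:2", "MS:1"}
    assert graph.closure("MS:1") == {"MS:1"}


def test_closure_is_idempotent():
    graph = cvmod.load_cv(CHAIN_OBO)
    members = graph.closure("MS:3")
    assert set().union(*(graph.closure(a) for a in members)) == members


def test_branch_membership_reflexive_and_antisymmetric():
    graph = cvmod.load_cv(CHAIN_OBO)
    assert graph.in_branch("MS:3", "MS:1")
    assert graph.in_branch("MS:3", "MS:3")
    assert not graph.in_branch("MS:1", "MS:3")


def test_unknown_accession_raises_lookup_error(subset):
    with pytest.raises(CvLookupError):
        subset.closure("MS:9999999")


def test_stanza_with_id_but_no_name_is_a_parse_error():
    with pytest.raises(OboParseError) as exc:
        cvmod.load_cv("[Term]\nid: MS:5\n")
    assert exc.value.line == 1


def test_malformed_line_is_a_parse_error_naming_the_line():
    with pytest.raises(OboParseError) as exc:
        cvmod.load_cv("[Term]\nid: MS:5\nname: ok\nnot a key value line\n")
    assert exc.value.line == 4


def test_is_a_cycle_is_a_structural_error():
    text = ("[Term]\nid: MS:1\nname: a\nis_a: MS:2\n\n"
            "[Term]\nid: MS:2\nname: b\nis_a: MS:1\n")
    with pytest.raises(CvStructureError):
        cvmod.load_cv(text)


def test_obsolete_terms_are_flagged(subset):
    assert subset["MS:9999001"].is_obsolete
    assert not subset["MS:1002490"].is_obsolete


def test_obo_round_trip_preserves_the_term_set(subset):
    reloaded = cvmod.load_cv(cvmod.write_obo(subset), source_cv="MS")
    assert reloaded.terms == subset.terms


def test_vendored_subset_agrees_with_obonet():
    """Independent OBO reader sees the same terms and is_a edges."""
    obonet = pytest.importorskip("obonet")
    text = (cvmod.files("mzidkit") / "data" / "psi-ms-subset.obo").read_text("utf-8")
    graph = obonet.read_obo(io.StringIO(text))
    ours = cvmod.load_psi_ms_subset()
    live = {a for a, t in ours.terms.items() if not t.is_obsolete}
    assert set(graph.nodes) == live
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            assert parent in ours[child].parents


def test_xlmod_stub_loads_and_merges(subset):
    merged = subset.merged_with(cvmod.load_xlmod_stub())
    assert merged.in_branch("XLMOD:02001", "XLMOD:00000")
    assert merged["XLMOD:02001"].source_cv == "XLMOD"
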
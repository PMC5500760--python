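"""Generator contract: determinism and workflow-characteristic structures."""

import pytest

from mzidkit import io as mzio
from mzidkit import synth
from mzidkit import terms as t
from mzidkit.errors import ParameterError


def test_identical_seed_and_params_give_byte_identical_files():
    a = mzio.write_mzid(synth.generate(t.CROSS_LINKING_SEARCH, seed=7))
    b = mzio.write_mzid(synth.generate(t.CROSS_LINKING_SEARCH, seed=7))
    assert a == b


def test_different_seeds_give_different_files():
    a = mzio.write_mzid(synth.generate(t.NO_SPECIAL_PROCESSING, seed=1))
    b = mzio.write_mzid(synth.generate(t.NO_SPECIAL_PROCESSING, seed=2))
    assert a != b


def test_unknown_workflow_is_a_parameter_error():
    with pytest.raises(ParameterError):
        synth.generate("MS:9999999")


def test_declared_flag_matches_the_requested_workflow(make_doc):
    for workflow in synth.WORKFLOWS:
        assert workflow in make_doc(workflow, seed=1).workflow_flags()


def test_prefractionation_has_three_lists_and_one_protein_list(make_doc):
    doc = make_doc(t.SAMPLE_PREFRACTIONATION, seed=1)
    assert len(doc.spectrum_identification_lists) == 3
    assert len(doc.protein_detection_lists) == 1
    assert doc.protein_detection is not None


def test_crosslink_fixture_follows_the_donor_acceptor_convention(make_doc):
    doc = make_doc(t.CROSS_LINKING_SEARCH, n_spectra=5, seed=2)
    donors = acceptors = 0
    for pep in doc.peptides:
        for mod in pep.modifications:
            if mod.param(t.CROSS_LINK_DONOR) is not None:
                donors += 1
                assert mod.monoisotopic_mass_delta != 0
            if mod.param(t.CROSS_LINK_ACCEPTOR) is not None:
                acceptors += 1
                assert mod.monoisotopic_mass_delta == 0
    assert donors == acceptors == 5


def test_localization_fixture_covers_the_position_conventions(make_doc):
    doc = make_doc(t.MODIFICATION_LOCALIZATION_SCORING, seed=1)
    index = doc.index()
    values = []
    for _s, _r, item in doc.iter_items():
        for p in item.cv_params:
            if p.accession == "MS:1002546":
                pep = index[item.peptide_ref]
                values.append((p.value, len(pep.sequence)))
    assert any("|" in v.split(":")[2] for v, _ in values)
    assert any(v.split(":")[2] == "0" for v, _ in values)
    assert any(v.split(":")[2] == str(n + 1) for v, n in values)
    # every modification carries exactly one index term
    for pep in doc.peptides:
        for mod in pep.modifications:
            idx = [p for p in mod.cv_params
                   if p.accession == t.MODIFICATION_INDEX]
            assert len(idx) == 1


def test_db_free_fixtures_have_zero_evidence_psms(make_doc):
    for workflow in (t.DE_NOVO_SEARCH, t.SPECTRAL_LIBRARY_SEARCH):
        doc = make_doc(workflow, seed=1)
        assert all(not item.peptide_evidence_refs
                   for _s, _r, item in doc.iter_items())
    library = make_doc(t.SPECTRAL_LIBRARY_SEARCH, seed=1)
    assert any(pep.sequence == "" for pep in library.peptides)


def test_peptide_level_fixture_carries_group_annotations(make_doc):
    doc = make_doc(t.PEPTIDE_LEVEL_SCORING, seed=1)
    for _s, _r, item in doc.iter_items():
        assert item.param(t.PEPTIDE_GROUP_ID) is not None
        assert item.param(t.PEPTIDE_QVALUE) is not None
    modes = [p.accession for p in doc.protocols[0].additional_search_params
             if p.accession in t.GROUPING_MODES]
    assert len(modes) == 1


def test_corrupt_rejects_unknown_or_inapplicable_defects(make_doc):
    doc = make_doc(t.NO_SPECIAL_PROCESSING, seed=1)
    with pytest.raises(ParameterError):
        synth.corrupt(doc, "NOT-A-RULE")
    with pytest.raises(ParameterError):
        synth.corrupt(doc, "XL-2")  # no cross-link structures present


def test_corrupt_does_not_mutate_the_input(make_doc):
    doc = make_doc(t.NO_SPECIAL_PROCESSING, seed=1)
    before = mzio.write_mzid(doc)
    synth.corrupt(doc, "CARD-1")
    assert mzio.write_mzid(doc) == before
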
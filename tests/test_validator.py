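"""Semantic validator: flag gating, conditional rules, levels, reports."""

import copy
import json

import pytest

from mzidkit import model as m
from mzidkit import synth
from mzidkit import terms as t
from mzidkit import validator as val
from mzidkit.model import SpectraData


def errors(messages):
    return [msg for msg in messages if msg.level == "error"]


def test_every_workflow_fixture_validates_clean(make_doc):
    for workflow in synth.WORKFLOWS:
        messages = val.validate(make_doc(workflow, seed=1))
        assert errors(messages) == [], (workflow, messages[:3])


def test_flag_rule_fires_only_on_flagless_12_documents(make_doc):
    doc12 = synth.corrupt(make_doc(t.NO_SPECIAL_PROCESSING, seed=1), "FLAG-1")
    assert {msg.rule_id for msg in errors(val.validate(doc12))} == {"FLAG-1"}

    doc11 = synth.generate(t.NO_SPECIAL_PROCESSING, seed=1, version="1.1.0")
    doc11 = synth.corrupt(doc11, "FLAG-1")
    assert not any(msg.rule_id == "FLAG-1" for msg in val.validate(doc11))


def test_multiple_flags_are_allowed(make_doc):
    doc = copy.deepcopy(make_doc(t.NO_SPECIAL_PROCESSING, seed=1))
    doc.protocols[0].additional_search_params.append(
        m.CvParam(t.SAMPLE_PREFRACTIONATION, "sample pre-fractionation"))
    assert not any(msg.rule_id == "FLAG-1" for msg in val.validate(doc))


def test_level_mapping_may_should_must():
    doc = synth.generate(t.NO_SPECIAL_PROCESSING, seed=1)
    # a branch no fixture ever uses, at each requirement level
    rules = [
        val.CvRule("R-MAY", "Peptide", "MAY", ("MS:1002545",), min=1),
        val.CvRule("R-SHOULD", "Peptide", "SHOULD", ("MS:1002545",), min=1),
        val.CvRule("R-MUST", "Peptide", "MUST", ("MS:1002545",), min=1),
    ]
    levels = {msg.rule_id: msg.level for msg in val.validate(doc, ruleset=rules)}
    assert levels["R-MAY"] == "info"
    assert levels["R-SHOULD"] == "warning"
    assert levels["R-MUST"] == "error"


def test_rule_cardinality_must_be_consistent():
    with pytest.raises(ValueError):
        val.CvRule("R", "Peptide", "MUST", ("MS:1",), min=2, max=1)
    with pytest.raises(ValueError):
        val.CvRule("R", "Peptide", "PLEASE", ("MS:1",))


@pytest.mark.parametrize("rule_id", synth.RULE_IDS)
def test_each_seeded_defect_triggers_exactly_its_rule(rule_id, make_doc):
    doc = make_doc(synth.FIXTURE_FOR_DEFECT[rule_id], seed=1)
    messages = val.validate(synth.corrupt(doc, rule_id))
    assert any(msg.rule_id == rule_id for msg in messages), rule_id
    assert {msg.rule_id for msg in errors(messages)} <= {rule_id}


def test_pep4_is_a_warning_not_an_error(make_doc):
    doc = synth.corrupt(make_doc(t.PEPTIDE_LEVEL_SCORING, seed=1), "PEP-4")
    pep4 = [msg for msg in val.validate(doc) if msg.rule_id == "PEP-4"]
    assert pep4 and all(msg.level == "warning" for msg in pep4)


def test_spectrum_uniqueness_is_keyed_on_the_spectra_data_pair(make_doc):
    doc = copy.deepcopy(make_doc(t.NO_SPECIAL_PROCESSING, seed=1))
    doc.spectra_data.append(SpectraData("SD_2", "file:///data/run2.mgf"))
    results = doc.spectrum_identification_lists[0].results
    results[1].spectrum_id = results[0].spectrum_id
    results[1].spectra_data_ref = "SD_2"
    for si in doc.spectrum_identifications:
        si.spectra_data_refs.append("SD_2")
    assert not any(msg.rule_id == "UNIQ-1" for msg in val.validate(doc))

    results[1].spectra_data_ref = results[0].spectra_data_ref
    assert any(msg.rule_id == "UNIQ-1" for msg in errors(val.validate(doc)))


def test_uniqueness_rule_can_be_switched_off(make_doc):
    doc = synth.corrupt(make_doc(t.NO_SPECIAL_PROCESSING, seed=1), "UNIQ-1")
    config = val.ValidatorConfig(unique_spectrum_ids=False)
    assert not any(msg.rule_id == "UNIQ-1"
                   for msg in val.validate(doc, config=config))


def test_score_identity_tolerance_mode(make_doc):
    doc = copy.deepcopy(make_doc(t.CROSS_LINKING_SEARCH, seed=1))
    item = doc.spectrum_identification_lists[0].results[0].items[1]
    p = item.param(t.MSGF_RAW_SCORE)
    p.value = repr(float(p.value) + 1e-9)  # numerically equal, textually not
    assert any(msg.rule_id == "XL-4" for msg in errors(val.validate(doc)))
    tol = val.ValidatorConfig(score_tolerance=1e-6)
    assert not any(msg.rule_id == "XL-4"
                   for msg in val.validate(doc, config=tol))


def test_messages_are_deterministically_ordered(make_doc):
    doc = synth.corrupt(make_doc(t.PROTEOGENOMICS_SEARCH, seed=1), "PG-2")
    assert val.validate(doc) == val.validate(doc)


def test_ruleset_loads_from_json_file(tmp_path):
    path = tmp_path / "rules.json"
    path.write_text(json.dumps({"rules": [
        {"rule_id": "X-1", "scope": "DBSequence", "level": "SHOULD",
         "branch_roots": ["MS:1002637"], "min": 1},
    ]}))
    rules = val.load_ruleset(str(path))
    assert rules[0].rule_id == "X-1" and rules[0].level == "SHOULD"


def test_reports_render_tsv_and_json(make_doc):
    messages = val.validate(
        synth.corrupt(make_doc(t.NO_SPECIAL_PROCESSING, seed=1), "CARD-1"))
    tsv = val.report_tsv(messages)
    assert tsv.startswith("rule_id\tlevel\tlocus\ttext")
    parsed = json.loads(val.report_json(messages))
    assert any(entry["rule_id"] == "CARD-1" for entry in parsed)
    assert not val.is_valid(messages)
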
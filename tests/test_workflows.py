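"""Workflow feature layer: localization codec, cross-link pairing,
peptide grouping/FDR, genomic mappings."""

import copy
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzidkit import model as m
from mzidkit import synth
from mzidkit import terms as t
from mzidkit import workflows as wf
from mzidkit.errors import (
    AnnotationError,
    CrossLinkError,
    MappingError,
    ScoreGrammarError,
    ScoreRangeError,
    ScoreReferenceError,
)

LOC_TERM = "MS:1002546"


def _indexed_peptide(sequence="DNSTMGYMMAK", n_mods=2):
    mods = [
        m.Modification(
            location=i + 3, monoisotopic_mass_delta=79.966331,
            cv_params=[
                m.CvParam("UNIMOD:21", "Phospho", cv_ref="UNIMOD"),
                m.CvParam(t.MODIFICATION_INDEX, "modification index",
                          value=str(i + 1)),
            ],
        )
        for i in range(n_mods)
    ]
    return m.Peptide(id="PEP_X", sequence=sequence, modifications=mods)


def _loc(value):
    return m.CvParam(LOC_TERM, "localization site probability", value=value)


class TestLocalizationCodec:
    @pytest.mark.parametrize("value, index, score, positions, passed", [
        ("1:45.3:4:true", 1, 45.3, (4,), True),
        ("1:0.88:3|5:false", 1, 0.88, (3, 5), False),
        ("1:10.0:0:true", 1, 10.0, (0,), True),          # N-terminus
        ("1:10.0:12:true", 1, 10.0, (12,), True),        # C-terminus, len 11
        ("2:1e-3:4:TRUE", 2, 1e-3, (4,), True),
    ])
    def test_valid_values_decode(self, value, index, score, positions, passed):
        ls = wf.parse_localization_score(_loc(value), _indexed_peptide())
        assert (ls.mod_index, ls.score, ls.positions, ls.pass_threshold) == \
            (index, score, positions, passed)

    @pytest.mark.parametrize("value", [
        "1:45.3:4",              # three fields
        "1:45.3:4:true:extra",
        "one:45.3:4:true",
        "1:high:4:true",
        "1:45.3:x|2:true",
        "1:45.3:4:maybe",
        "1:45.3:4|4:true",       # duplicate position
    ])
    def test_grammar_violations(self, value):
        with pytest.raises(ScoreGrammarError):
            wf.parse_localization_score(_loc(value), _indexed_peptide())

    def test_unresolvable_mod_index(self):
        with pytest.raises(ScoreReferenceError):
            wf.parse_localization_score(_loc("9:45.3:4:true"), _indexed_peptide())

    def test_position_outside_the_peptide(self):
        with pytest.raises(ScoreRangeError):
            wf.parse_localization_score(_loc("1:45.3:13:true"), _indexed_peptide())

    def test_emit_refuses_empty_positions(self):
        ls = wf.LocalizationScore(LOC_TERM, 1, 5.0, (), True)
        with pytest.raises(ScoreGrammarError):
            wf.emit_localization_score(ls)

    @settings(max_examples=200, derandomize=True)
    @given(
        index=st.integers(1, 2),
        score=st.floats(allow_nan=False, allow_infinity=False, width=64),
        positions=st.sets(st.integers(0, 12), min_size=1, max_size=4),
        passed=st.booleans(),
    )
    def test_parse_emit_inverse(self, index, score, positions, passed):
        ls = wf.LocalizationScore(LOC_TERM, index, float(score),
                                  tuple(sorted(positions)), passed)
        back = wf.parse_localization_score(
            wf.emit_localization_score(ls), _indexed_peptide())
        assert back == ls


class TestConfidentSites:
    def _doc(self, score_value, start=100):
        doc = m.Document()
        pep = _indexed_peptide()
        doc.peptides.append(pep)
        doc.search_databases.append(m.SearchDatabase("SDB_1", "file:///db"))
        doc.db_sequences.append(m.DBSequence("DBS_1", "PROT_1", "SDB_1"))
        doc.peptide_evidences.append(m.PeptideEvidence(
            "PE_1", pep.id, "DBS_1", start=start,
            end=None if start is None else start + len(pep.sequence) - 1))
        doc.spectra_data.append(m.SpectraData("SD_1", "file:///mgf"))
        sil = m.SpectrumIdentificationList("SIL_1", results=[
            m.SpectrumIdentificationResult(
                "SIR_1", "index=0", "SD_1", items=[
                    m.SpectrumIdentificationItem(
                        "SII_1", 1, 2, 500.0, pep.id,
                        peptide_evidence_refs=["PE_1"],
                        cv_params=[_loc(score_value)]),
                ])])
        doc.spectrum_identification_lists.append(sil)
        return doc

    def test_unambiguous_passing_site_maps_to_protein_coordinates(self):
        sites = wf.confident_sites(self._doc("1:45.3:4:true"))
        assert sites == [("PROT_1", 103, "UNIMOD:21", 45.3)]

    def test_ambiguous_positions_are_excluded_even_when_passing(self):
        assert wf.confident_sites(self._doc("1:45.3:3|5:true")) == []

    def test_below_threshold_sites_are_excluded(self):
        assert wf.confident_sites(self._doc("1:45.3:4:false")) == []

    def test_missing_evidence_start_skips_with_warning(self):
        doc = self._doc("1:45.3:4:true", start=None)
        with pytest.warns(UserWarning, match="start"):
            assert wf.confident_sites(doc) == []

    def test_duplicates_keep_the_best_score(self, make_doc):
        doc = make_doc(t.MODIFICATION_LOCALIZATION_SCORING, seed=1)
        sites = wf.confident_sites(doc)
        assert sites, "fixture should yield confident sites"
        assert len({(a, p, mod) for a, p, mod, _ in sites}) == len(sites)


class TestCrossLinks:
    def test_fixture_results_resolve_one_pair_each(self, make_doc):
        doc = make_doc(t.CROSS_LINKING_SEARCH, n_spectra=5, seed=2)
        for sil in doc.spectrum_identification_lists:
            for result in sil.results:
                (pair,) = wf.resolve_crosslink_pairs(result, doc)
                assert len(pair.sii_ids) == 2
                assert pair.shared_scores
                assert pair.acceptor_peptide_refs

    def test_result_without_pairing_terms_yields_no_pairs(self, make_doc):
        doc = make_doc(t.NO_SPECIAL_PROCESSING, seed=1)
        result = doc.spectrum_identification_lists[0].results[0]
        assert wf.resolve_crosslink_pairs(result, doc) == []

    def _chain_doc(self, n_acceptors=2, ranks=None, drop_donor=False):
        """One donor and n acceptors sequentially linked in one spectrum."""
        doc = m.Document()
        doc.spectra_data.append(m.SpectraData("SD_1", "file:///mgf"))
        doc.search_databases.append(m.SearchDatabase("SDB_1", "file:///db"))
        items = []
        for i in range(n_acceptors + 1):
            donor = i == 0 and not drop_donor
            params = []
            if i == 0 and not drop_donor:
                params = [m.CvParam(t.CROSS_LINK_DONOR, "cross-link donor",
                                    value="XL7")]
            elif i > 0:
                params = [m.CvParam(t.CROSS_LINK_ACCEPTOR, "cross-link acceptor",
                                    value="XL7")]
            pep = m.Peptide(
                id=f"PEP_{i}", sequence="KAAAAAAK",
                modifications=[m.Modification(
                    location=1,
                    monoisotopic_mass_delta=138.06808 if donor else 0.0,
                    cv_params=params or [m.CvParam("XLMOD:02001", "DSS",
                                                   cv_ref="XLMOD")],
                )])
            doc.peptides.append(pep)
            doc.db_sequences.append(m.DBSequence(f"DBS_{i}", f"P{i}", "SDB_1"))
            doc.peptide_evidences.append(
                m.PeptideEvidence(f"PE_{i}", pep.id, f"DBS_{i}", start=1, end=8))
            items.append(m.SpectrumIdentificationItem(
                f"SII_{i}", (ranks or [2] * (n_acceptors + 1))[i], 3, 700.0,
                pep.id, peptide_evidence_refs=[f"PE_{i}"],
                cv_params=[
                    m.CvParam(t.MSGF_RAW_SCORE, "MS-GF:RawScore", value="88.0"),
                    m.CvParam(t.CROSS_LINK_SII,
                              "cross-link spectrum identification item",
                              value="7"),
                ]))
        doc.spectrum_identification_lists.append(m.SpectrumIdentificationList(
            "SIL_1", results=[m.SpectrumIdentificationResult(
                "SIR_1", "index=0", "SD_1", items=items)]))
        return doc

    def test_sequential_chain_of_three_forms_one_pair(self):
        doc = self._chain_doc(n_acceptors=2)
        (pair,) = wf.resolve_crosslink_pairs(
            doc.spectrum_identification_lists[0].results[0], doc)
        assert len(pair.sii_ids) == 3
        assert pair.link_value == "XL7"
        assert len(pair.acceptor_peptide_refs) == 2
        assert pair.shared_rank == 2

    def test_mixed_ranks_raise(self):
        doc = self._chain_doc(n_acceptors=1, ranks=[1, 2])
        with pytest.raises(CrossLinkError, match="rank"):
            wf.resolve_crosslink_pairs(
                doc.spectrum_identification_lists[0].results[0], doc)

    def test_missing_donor_raises(self):
        doc = self._chain_doc(n_acceptors=1, drop_donor=True)
        with pytest.raises(CrossLinkError, match="donor"):
            wf.resolve_crosslink_pairs(
                doc.spectrum_identification_lists[0].results[0], doc)

    def test_unpaired_value_raises(self):
        doc = self._chain_doc(n_acceptors=1)
        result = doc.spectrum_identification_lists[0].results[0]
        del result.items[1]
        with pytest.raises(CrossLinkError, match="unpaired"):
            wf.resolve_crosslink_pairs(result, doc)


def _grouping_doc():
    """PEPTIDER modified + unmodified, at charges 2 and 3."""
    doc = m.Document()
    doc.spectra_data.append(m.SpectraData("SD_1", "file:///mgf"))
    plain = m.Peptide(id="PEP_plain", sequence="PEPTIDER")
    phospho = m.Peptide(id="PEP_phos", sequence="PEPTIDER", modifications=[
        m.Modification(location=3, monoisotopic_mass_delta=79.966331,
                       cv_params=[m.CvParam("UNIMOD:21", "Phospho",
                                            cv_ref="UNIMOD")])])
    doc.peptides.extend([plain, phospho])
    items = [
        ("SII_1", plain, 2), ("SII_2", phospho, 2), ("SII_3", plain, 3),
    ]
    results = []
    for i, (sid, pep, z) in enumerate(items):
        results.append(m.SpectrumIdentificationResult(
            f"SIR_{i}", f"index={i}", "SD_1", items=[
                m.SpectrumIdentificationItem(
                    sid, 1, z, 500.0, pep.id,
                    cv_params=[m.CvParam(t.MSGF_RAW_SCORE, "MS-GF:RawScore",
                                         value=f"{90 + i}")]),
            ]))
    doc.spectrum_identification_lists.append(
        m.SpectrumIdentificationList("SIL_1", results=results))
    return doc


class TestGrouping:
    def test_modified_and_unmodified_collapse_under_sequence(self):
        doc = _grouping_doc()
        sil = doc.spectrum_identification_lists[0]
        assert len(wf.group_psms(sil, doc, wf.GroupingMode.SEQUENCE)) == 1
        assert len(wf.group_psms(sil, doc, wf.GroupingMode.SEQUENCE_MODS)) == 2
        assert len(wf.group_psms(sil, doc,
                                 wf.GroupingMode.SEQUENCE_MODS_CHARGE)) == 3

    def test_groups_partition_the_psm_set(self, make_doc):
        doc = make_doc(t.PEPTIDE_LEVEL_SCORING, n_spectra=60, seed=3)
        sil = doc.spectrum_identification_lists[0]
        all_ids = {item.id for _s, _r, item in doc.iter_items()}
        for mode in wf.GroupingMode:
            seen = [sid for g in wf.group_psms(sil, doc, mode)
                    for sid in g.member_sii_ids]
            assert sorted(seen) == sorted(all_ids)
            assert len(seen) == len(set(seen))

    def test_refinement_chain(self, make_doc):
        doc = make_doc(t.PEPTIDE_LEVEL_SCORING, n_spectra=60, seed=3)
        sil = doc.spectrum_identification_lists[0]
        partitions = {
            mode: {g.group_id: set(g.member_sii_ids)
                   for g in wf.group_psms(sil, doc, mode)}
            for mode in wf.GroupingMode
        }
        chain = [wf.GroupingMode.SEQUENCE_MODS_CHARGE,
                 wf.GroupingMode.SEQUENCE_MODS, wf.GroupingMode.SEQUENCE]
        for finer, coarser in zip(chain, chain[1:]):
            for members in partitions[finer].values():
                assert any(members <= coarse
                           for coarse in partitions[coarser].values())


def brute_force_qvalues(groups, higher_is_better=True):
    """Independent O(n^2) prefix-counting q-value oracle."""
    ordered = sorted(
        groups,
        key=lambda g: ((-g.best_psm_score if higher_is_better
                        else g.best_psm_score), g.group_id))
    qs = []
    for k in range(1, len(ordered) + 1):
        best = float("inf")
        for j in range(k, len(ordered) + 1):
            prefix = ordered[:j]
            decoys = sum(1 for g in prefix if g.is_decoy)
            targets = sum(1 for g in prefix if not g.is_decoy)
            best = min(best, decoys / max(1, targets))
        qs.append(best)
    return {g.group_id: q for g, q in zip(ordered, qs)}


def _random_groups(rng, n=50):
    return [
        wf.PeptideGroup(
            group_id=f"G{i}", mode=wf.GroupingMode.SEQUENCE,
            member_sii_ids=[f"S{i}"], is_decoy=rng.random() < 0.4,
            best_psm_score=round(rng.gauss(80, 15), 3))
        for i in range(n)
    ]


class TestPeptideFdr:
    def test_no_decoys_means_all_zero_q(self):
        rng = random.Random(0)
        groups = _random_groups(rng, 20)
        for g in groups:
            g.is_decoy = False
        assert all(g.q_value == 0.0 for g in wf.peptide_fdr(groups))

    def test_decoys_at_the_bottom_leave_targets_at_zero(self):
        groups = [wf.PeptideGroup(f"G{i}", wf.GroupingMode.SEQUENCE, [f"S{i}"],
                                  is_decoy=i >= 8, best_psm_score=100 - i)
                  for i in range(10)]
        annotated = wf.peptide_fdr(groups)
        assert all(g.q_value == 0.0 for g in annotated if not g.is_decoy)

    def test_alternating_targets_and_decoys_match_the_oracle(self):
        groups = [wf.PeptideGroup(f"G{i}", wf.GroupingMode.SEQUENCE, [f"S{i}"],
                                  is_decoy=bool(i % 2), best_psm_score=100 - i)
                  for i in range(4)]
        oracle = brute_force_qvalues(groups)
        for g in wf.peptide_fdr(groups):
            assert g.q_value == oracle[g.group_id]

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_random_instances_match_the_oracle(self, seed):
        groups = _random_groups(random.Random(seed))
        oracle = brute_force_qvalues(groups)
        annotated = wf.peptide_fdr(groups)
        for g in annotated:
            assert g.q_value == pytest.approx(oracle[g.group_id], abs=0)
        qs = [g.q_value for g in annotated]
        assert qs == sorted(qs)  # monotone along the sorted order

    def test_all_decoy_input_warns_but_defines_q(self):
        groups = [wf.PeptideGroup(f"G{i}", wf.GroupingMode.SEQUENCE, [f"S{i}"],
                                  is_decoy=True, best_psm_score=float(i))
                  for i in range(3)]
        with pytest.warns(UserWarning, match="decoy"):
            annotated = wf.peptide_fdr(groups)
        assert all(g.q_value is not None for g in annotated)


class TestAnnotations:
    def test_annotated_fixture_revalidates_clean(self, make_doc):
        from mzidkit import validator as val
        for mode in wf.GroupingMode:
            doc = synth.generate(t.PEPTIDE_LEVEL_SCORING, seed=4,
                                 grouping_mode=mode)
            msgs = [msg for msg in val.validate(doc) if msg.level == "error"]
            assert msgs == [], (mode, msgs[:3])

    def test_reannotation_with_another_grouping_is_refused(self, make_doc):
        doc = copy.deepcopy(make_doc(t.PEPTIDE_LEVEL_SCORING, seed=1))
        sil = doc.spectrum_identification_lists[0]
        groups = wf.peptide_fdr(
            wf.group_psms(sil, doc, wf.GroupingMode.SEQUENCE_MODS))
        with pytest.raises(AnnotationError):
            wf.apply_peptide_annotations(doc, groups, threshold=0.01)

    def test_threshold_marks_pass_threshold(self):
        doc = _grouping_doc()
        # make one decoy group so a q-value exceeds the threshold
        doc.search_databases.append(m.SearchDatabase("SDB_1", "file:///db"))
        doc.db_sequences.append(m.DBSequence("DBS_1", "DECOY_P", "SDB_1"))
        doc.peptide_evidences.append(m.PeptideEvidence(
            "PE_D", "PEP_plain", "DBS_1", is_decoy=True))
        for _s, _r, item in doc.iter_items():
            item.peptide_evidence_refs = ["PE_D"]
        sil = doc.spectrum_identification_lists[0]
        with pytest.warns(UserWarning, match="decoy"):
            groups = wf.peptide_fdr(
                wf.group_psms(sil, doc, wf.GroupingMode.SEQUENCE))
        wf.apply_peptide_annotations(doc, groups, threshold=0.01)
        assert all(not item.pass_threshold for _s, _r, item in doc.iter_items())


class TestGenomicMappings:
    def _evidence(self, starts, ends, exons):
        return m.PeptideEvidence(
            "PE_1", "PEP_1", "DBS_1", start=1, end=9, cv_params=[
                m.CvParam(t.DEFAULT_REGISTRY.pg_start_positions, "starts",
                          value=starts),
                m.CvParam(t.DEFAULT_REGISTRY.pg_end_positions, "ends",
                          value=ends),
                m.CvParam(t.DEFAULT_REGISTRY.pg_exon_count, "exons",
                          value=exons),
            ])

    def _dbs(self):
        return m.DBSequence("DBS_1", "PROT_1", "SDB_1", cv_params=[
            m.CvParam(t.DEFAULT_REGISTRY.pg_genome_build, "build",
                      value="GRCh38"),
            m.CvParam(t.DEFAULT_REGISTRY.pg_chromosome, "chrom", value="chr7"),
            m.CvParam(t.DEFAULT_REGISTRY.pg_strand, "strand", value="+"),
        ])

    def test_single_exon_nine_residues(self):
        pep = m.Peptide("PEP_1", "ACDEFGHIK")
        gm = wf.genomic_mapping(self._evidence("101", "127", "1"),
                                self._dbs(), pep)
        assert gm.blocks == ((101, 127),)
        assert gm.exon_count == 1

    def test_junction_spanning_two_blocks(self):
        pep = m.Peptide("PEP_1", "ACDEFGHIKL")  # 10 residues, 30 nt
        gm = wf.genomic_mapping(
            self._evidence("101,1000", "112,1017", "2"), self._dbs(), pep)
        assert gm.blocks == ((101, 112), (1000, 1017))
        assert sum(e - s + 1 for s, e in gm.blocks) == 30

    def test_coding_length_mismatch_is_an_error(self):
        pep = m.Peptide("PEP_1", "ACDEFGHIKL")
        with pytest.raises(MappingError, match="nt"):
            wf.genomic_mapping(self._evidence("101", "129", "1"),
                               self._dbs(), pep)

    def test_exon_count_mismatch_is_an_error(self):
        pep = m.Peptide("PEP_1", "ACDEFGHIK")
        with pytest.raises(MappingError, match="exon"):
            wf.genomic_mapping(self._evidence("101", "127", "2"),
                               self._dbs(), pep)

    def test_missing_param_is_an_error(self):
        pep = m.Peptide("PEP_1", "ACDEFGHIK")
        dbs = self._dbs()
        dbs.cv_params = dbs.cv_params[:-1]  # drop strand
        with pytest.raises(MappingError, match="1002638"):
            wf.genomic_mapping(self._evidence("101", "127", "1"), dbs, pep)


class TestBed:
    def test_coordinate_convention_single_block(self):
        gm = wf.GenomicMapping("chr7", "+", "GRCh38", ((101, 127),), 1)
        line = wf.export_bed([("pep1", gm)]).strip().split("\t")
        assert (line[0], line[1], line[2], line[5]) == ("chr7", "100", "127", "+")
        assert line[9] == "1" and line[10] == "27"

    def test_minus_strand_blocks_stay_ascending(self):
        gm = wf.GenomicMapping("chr2", "-", "GRCh38",
                               ((101, 112), (1000, 1017)), 2)
        line = wf.export_bed([("pep2", gm)]).strip().split("\t")
        assert line[5] == "-" and line[9] == "2"
        assert line[10] == "12,18" and line[11] == "0,899"

    def test_export_reimports_to_identical_blocks(self, make_doc):
        doc = make_doc(t.PROTEOGENOMICS_SEARCH, seed=1)
        mappings = wf.all_genomic_mappings(doc)
        back = wf.read_bed(wf.export_bed(mappings))
        assert [(n, g.chromosome, g.strand, g.blocks) for n, g in mappings] \
            == [(n, g.chromosome, g.strand, g.blocks) for n, g in back]
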
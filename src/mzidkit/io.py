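"""mzIdentML 1.1 / 1.2 XML reading and writing.

The two schema series are nearly identical, so version handling is purely
declarative: the namespace and the root ``version`` attribute decide how a
file is treated, never structural sniffing.  Writing is deterministic —
elements are emitted in schema order with siblings sorted by identifier
(PSMs by rank, then id), so two writes of the same document are
byte-identical and output diffs are meaningful.
"""

from __future__ import annotations

import io as _io
from importlib.resources import files
from typing import IO, Union

from lxml import etree

from . import model as m
from .errors import (
    NotMzIdentMLError,
    SerializationError,
    VersionError,
)

NAMESPACES = {
    "1.1": "http://psidev.info/psi/pi/mzIdentML/1.1",
    "1.2": "http://psidev.info/psi/pi/mzIdentML/1.2",
}
_NS_TO_SERIES = {v: k for k, v in NAMESPACES.items()}

_SCHEMA_FILES = {
    "1.1": "mzid-1.1-subset_synthetic.xsd",
    "1.2": "mzid-1.2-subset_synthetic.xsd",
}

_ROOT_ORDER = (
    "cvList",
    "AnalysisSoftwareList",
    "SequenceCollection",
    "AnalysisCollection",
    "AnalysisProtocolCollection",
    "DataCollection",
)

Source = Union[str, bytes, IO[bytes]]


def _as_bytes(source: Source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, str):
        if source.lstrip().startswith("<"):
            return source.encode("utf-8")
        with open(source, "rb") as fh:
            return fh.read()
    return source.read()


def _series(version: str) -> str:
    for series in NAMESPACES:
        if version.startswith(series):
            return series
    raise VersionError(f"unsupported mzIdentML version {version!r}")


def _local(el) -> str:
    return etree.QName(el).localname


def _bool(text: str | None, default: bool | None = None) -> bool:
    if text is None:
        if default is None:
            raise VersionError("missing boolean attribute")
        return default
    return text.strip().lower() in ("true", "1")


def detect_version(source: Source) -> str:
    """Read the root ``version`` attribute without materialising the document."""
    data = _as_bytes(source)
    for _event, el in etree.iterparse(_io.BytesIO(data), events=("start",)):
        version = el.get("version")
        if version is None:
            raise VersionError("root element has no version attribute")
        return version
    raise VersionError("empty XML input")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_param(el) -> m.CvParam | m.UserParam:
    if _local(el) == "userParam":
        return m.UserParam(name=el.get("name", ""), value=el.get("value"))
    return m.CvParam(
        accession=el.get("accession", ""),
        name=el.get("name", ""),
        value=el.get("value"),
        cv_ref=el.get("cvRef", ""),
        unit_accession=el.get("unitAccession"),
        unit_name=el.get("unitName"),
    )


def _child_params(el, *names: str) -> list:
    wanted = names or ("cvParam", "userParam")
    return [_parse_param(c) for c in el if _local(c) in wanted]


def _single_param(el) -> m.CvParam | m.UserParam:
    for c in el:
        if _local(c) in ("cvParam", "userParam"):
            return _parse_param(c)
    raise NotMzIdentMLError(f"<{_local(el)}> has no cvParam/userParam child")


def parse_mzid(source: Source) -> m.Document:
    """Parse an mzIdentML stream into a :class:`~mzidkit.model.Document`.

    Raises :class:`NotMzIdentMLError` for foreign namespaces,
    :class:`VersionError` for a missing/unsupported version attribute and
    :class:`DanglingReferenceError` when the reference graph is not closed.
    """
    data = _as_bytes(source)
    root = etree.fromstring(data)
    ns = etree.QName(root).namespace
    if ns not in _NS_TO_SERIES:
        raise NotMzIdentMLError(f"root namespace {ns!r} is not mzIdentML")
    if _local(root) != "MzIdentML":
        raise NotMzIdentMLError(f"unexpected root element <{_local(root)}>")
    version = root.get("version")
    if version is None:
        raise VersionError("root element has no version attribute")
    _series(version)

    doc = m.Document(version=version)
    for pos, child in enumerate(root):
        name = _local(child)
        if name == "cvList":
            for cv in child:
                doc.cvs.append(m.Cv(
                    id=cv.get("id", ""), full_name=cv.get("fullName", ""),
                    uri=cv.get("uri", ""), version=cv.get("version"),
                ))
        elif name == "AnalysisSoftwareList":
            for sw in child:
                (software_name,) = [c for c in sw if _local(c) == "SoftwareName"]
                doc.analysis_software.append(m.AnalysisSoftware(
                    id=sw.get("id", ""),
                    software_name=_single_param(software_name),
                    name=sw.get("name"), version=sw.get("version"),
                ))
        elif name == "SequenceCollection":
            _parse_sequence_collection(child, doc)
        elif name == "AnalysisCollection":
            _parse_analysis_collection(child, doc)
        elif name == "AnalysisProtocolCollection":
            _parse_protocols(child, doc)
        elif name == "DataCollection":
            _parse_data_collection(child, doc)
        else:
            import copy as _copy
            detached = _copy.deepcopy(child)
            detached.tail = None
            doc.extras.append((pos, etree.tostring(detached)))

    doc.index()          # duplicate-id enforcement
    doc.assert_closed()  # referential closure, listing each offender
    return doc


def _parse_sequence_collection(el, doc: m.Document) -> None:
    for child in el:
        name = _local(child)
        if name == "DBSequence":
            seq = None
            for c in child:
                if _local(c) == "Seq":
                    seq = c.text or ""
            doc.db_sequences.append(m.DBSequence(
                id=child.get("id", ""), accession=child.get("accession", ""),
                search_database_ref=child.get("searchDatabase_ref", ""),
                seq=seq, cv_params=_child_params(child, "cvParam"),
            ))
        elif name == "Peptide":
            sequence = ""
            mods: list[m.Modification] = []
            for c in child:
                if _local(c) == "PeptideSequence":
                    sequence = c.text or ""
                elif _local(c) == "Modification":
                    mods.append(m.Modification(
                        location=int(c.get("location", "0")),
                        monoisotopic_mass_delta=float(c.get("monoisotopicMassDelta", "0")),
                        residues=c.get("residues"),
                        cv_params=_child_params(c, "cvParam"),
                    ))
            doc.peptides.append(m.Peptide(
                id=child.get("id", ""), sequence=sequence, modifications=mods,
                cv_params=_child_params(child, "cvParam"),
            ))
        elif name == "PeptideEvidence":
            start = child.get("start")
            end = child.get("end")
            doc.peptide_evidences.append(m.PeptideEvidence(
                id=child.get("id", ""),
                peptide_ref=child.get("peptide_ref", ""),
                db_sequence_ref=child.get("dBSequence_ref", ""),
                start=int(start) if start is not None else None,
                end=int(end) if end is not None else None,
                pre=child.get("pre"), post=child.get("post"),
                is_decoy=_bool(child.get("isDecoy"), default=False),
                cv_params=_child_params(child, "cvParam"),
            ))


def _parse_analysis_collection(el, doc: m.Document) -> None:
    for child in el:
        if _local(child) == "SpectrumIdentification":
            doc.spectrum_identifications.append(m.SpectrumIdentification(
                id=child.get("id", ""),
                protocol_ref=child.get("spectrumIdentificationProtocol_ref", ""),
                sil_ref=child.get("spectrumIdentificationList_ref", ""),
                spectra_data_refs=[c.get("spectraData_ref", "")
                                   for c in child if _local(c) == "InputSpectra"],
                search_database_refs=[c.get("searchDatabase_ref", "")
                                      for c in child if _local(c) == "SearchDatabaseRef"],
            ))
        elif _local(child) == "ProteinDetection":
            doc.protein_detection = m.ProteinDetection(
                id=child.get("id", ""),
                protocol_ref=child.get("proteinDetectionProtocol_ref", ""),
                pdl_ref=child.get("proteinDetectionList_ref", ""),
                sil_refs=[c.get("spectrumIdentificationList_ref", "")
                          for c in child if _local(c) == "InputSpectrumIdentifications"],
            )


def _parse_protocols(el, doc: m.Document) -> None:
    for child in el:
        if _local(child) == "SpectrumIdentificationProtocol":
            search_type = m.CvParam("", "")
            additional: list = []
            threshold: list = []
            for c in child:
                if _local(c) == "SearchType":
                    search_type = _single_param(c)
                elif _local(c) == "AdditionalSearchParams":
                    additional = _child_params(c)
                elif _local(c) == "Threshold":
                    threshold = _child_params(c)
            doc.protocols.append(m.SpectrumIdentificationProtocol(
                id=child.get("id", ""),
                software_ref=child.get("analysisSoftware_ref", ""),
                search_type=search_type,
                additional_search_params=additional,
                threshold=threshold,
            ))
        elif _local(child) == "ProteinDetectionProtocol":
            analysis_params: list = []
            threshold = []
            for c in child:
                if _local(c) == "AnalysisParams":
                    analysis_params = _child_params(c)
                elif _local(c) == "Threshold":
                    threshold = _child_params(c)
            doc.protein_detection_protocol = m.ProteinDetectionProtocol(
                id=child.get("id", ""),
                software_ref=child.get("analysisSoftware_ref", ""),
                analysis_params=analysis_params,
                threshold=threshold,
            )


def _parse_data_collection(el, doc: m.Document) -> None:
    for section in el:
        if _local(section) == "Inputs":
            for child in section:
                if _local(child) == "SearchDatabase":
                    dbname: m.CvParam | m.UserParam = m.UserParam("database")
                    for c in child:
                        if _local(c) == "DatabaseName":
                            dbname = _single_param(c)
                    doc.search_databases.append(m.SearchDatabase(
                        id=child.get("id", ""), location=child.get("location", ""),
                        database_name=dbname,
                    ))
                elif _local(child) == "SpectraData":
                    ff = sf = m.CvParam("", "")
                    for c in child:
                        if _local(c) == "FileFormat":
                            ff = _single_param(c)
                        elif _local(c) == "SpectrumIDFormat":
                            sf = _single_param(c)
                    doc.spectra_data.append(m.SpectraData(
                        id=child.get("id", ""), location=child.get("location", ""),
                        file_format=ff, spectrum_id_format=sf,
                    ))
        elif _local(section) == "AnalysisData":
            for child in section:
                if _local(child) == "SpectrumIdentificationList":
                    doc.spectrum_identification_lists.append(_parse_sil(child))
                elif _local(child) == "ProteinDetectionList":
                    doc.protein_detection_lists.append(_parse_pdl(child))


def _parse_sil(el) -> m.SpectrumIdentificationList:
    sil = m.SpectrumIdentificationList(id=el.get("id", ""))
    for res in el:
        if _local(res) != "SpectrumIdentificationResult":
            continue
        result = m.SpectrumIdentificationResult(
            id=res.get("id", ""), spectrum_id=res.get("spectrumID", ""),
            spectra_data_ref=res.get("spectraData_ref", ""),
            cv_params=_child_params(res, "cvParam"),
        )
        for it in res:
            if _local(it) != "SpectrumIdentificationItem":
                continue
            calc = it.get("calculatedMassToCharge")
            result.items.append(m.SpectrumIdentificationItem(
                id=it.get("id", ""),
                rank=int(it.get("rank", "1")),
                charge_state=int(it.get("chargeState", "0")),
                experimental_mz=float(it.get("experimentalMassToCharge", "0")),
                calculated_mz=float(calc) if calc is not None else None,
                # mandatory in the schema; tolerate lenient files by defaulting
                pass_threshold=_bool(it.get("passThreshold"), default=True),
                peptide_ref=it.get("peptide_ref", ""),
                peptide_evidence_refs=[c.get("peptideEvidence_ref", "")
                                       for c in it if _local(c) == "PeptideEvidenceRef"],
                cv_params=_child_params(it, "cvParam"),
            ))
        sil.results.append(result)
    return sil


def _parse_pdl(el) -> m.ProteinDetectionList:
    pdl = m.ProteinDetectionList(id=el.get("id", ""),
                                 cv_params=_child_params(el, "cvParam"))
    for grp in el:
        if _local(grp) != "ProteinAmbiguityGroup":
            continue
        group = m.ProteinAmbiguityGroup(id=grp.get("id", ""),
                                        cv_params=_child_params(grp, "cvParam"))
        for hyp in grp:
            if _local(hyp) != "ProteinDetectionHypothesis":
                continue
            pdh = m.ProteinDetectionHypothesis(
                id=hyp.get("id", ""),
                db_sequence_ref=hyp.get("dBSequence_ref", ""),
                pass_threshold=_bool(hyp.get("passThreshold"), default=True),
                cv_params=_child_params(hyp, "cvParam"),
            )
            for ph in hyp:
                if _local(ph) != "PeptideHypothesis":
                    continue
                pdh.peptide_hypotheses.append(m.PeptideHypothesis(
                    peptide_evidence_ref=ph.get("peptideEvidence_ref", ""),
                    sii_refs=[c.get("spectrumIdentificationItem_ref", "")
                              for c in ph if _local(c) == "SpectrumIdentificationItemRef"],
                ))
            group.hypotheses.append(pdh)
        pdl.groups.append(group)
    return pdl


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_bool(x: bool) -> str:
    return "true" if x else "false"


def _emit_param(parent, param) -> None:
    if isinstance(param, m.UserParam):
        el = etree.SubElement(parent, _q(parent, "userParam"))
        el.set("name", param.name)
        if param.value is not None:
            el.set("value", param.value)
        return
    el = etree.SubElement(parent, _q(parent, "cvParam"))
    el.set("accession", param.accession)
    el.set("name", param.name)
    el.set("cvRef", param.cv_ref)
    if param.value is not None:
        el.set("value", param.value)
    if param.unit_accession is not None:
        el.set("unitAccession", param.unit_accession)
    if param.unit_name is not None:
        el.set("unitName", param.unit_name)


def _q(ref_el, name: str) -> str:
    return etree.QName(etree.QName(ref_el).namespace, name).text


def write_mzid(doc: m.Document, version: str | None = None) -> bytes:
    """Serialize *doc* as UTF-8 mzIdentML in the requested version series.

    Refuses documents that violate structural invariants (duplicate ids,
    more than one protein detection list, dangling references), naming the
    violated invariant.
    """
    version = version or doc.version
    series = _series(version)
    ns = NAMESPACES[series]

    try:
        doc.index()
    except Exception as exc:
        raise SerializationError(f"refusing to write: {exc}") from exc
    if len(doc.protein_detection_lists) > 1:
        raise SerializationError(
            "refusing to write: a file may contain only one ProteinDetectionList"
        )
    try:
        doc.assert_closed()
    except Exception as exc:
        raise SerializationError(f"refusing to write: {exc}") from exc

    root = etree.Element(etree.QName(ns, "MzIdentML").text, nsmap={None: ns})
    root.set("id", "MZID")
    root.set("version", version)

    sub = lambda parent, name: etree.SubElement(parent, etree.QName(ns, name).text)

    cvlist = sub(root, "cvList")
    for cv in doc.cvs:
        el = sub(cvlist, "cv")
        el.set("id", cv.id)
        el.set("fullName", cv.full_name)
        el.set("uri", cv.uri)
        if cv.version is not None:
            el.set("version", cv.version)

    if doc.analysis_software:
        swl = sub(root, "AnalysisSoftwareList")
        for sw in sorted(doc.analysis_software, key=lambda s: s.id):
            el = sub(swl, "AnalysisSoftware")
            el.set("id", sw.id)
            if sw.name is not None:
                el.set("name", sw.name)
            if sw.version is not None:
                el.set("version", sw.version)
            _emit_param(sub(el, "SoftwareName"), sw.software_name)

    if doc.db_sequences or doc.peptides or doc.peptide_evidences:
        seqc = sub(root, "SequenceCollection")
        for dbs in sorted(doc.db_sequences, key=lambda d: d.id):
            el = sub(seqc, "DBSequence")
            el.set("id", dbs.id)
            el.set("accession", dbs.accession)
            el.set("searchDatabase_ref", dbs.search_database_ref)
            if dbs.seq is not None:
                sub(el, "Seq").text = dbs.seq
            for p in dbs.cv_params:
                _emit_param(el, p)
        for pep in sorted(doc.peptides, key=lambda p: p.id):
            el = sub(seqc, "Peptide")
            el.set("id", pep.id)
            if pep.sequence:
                sub(el, "PeptideSequence").text = pep.sequence
            for mod in pep.modifications:
                me = sub(el, "Modification")
                me.set("location", str(mod.location))
                if mod.residues is not None:
                    me.set("residues", mod.residues)
                me.set("monoisotopicMassDelta", _fmt_float(mod.monoisotopic_mass_delta))
                for p in mod.cv_params:
                    _emit_param(me, p)
            for p in pep.cv_params:
                _emit_param(el, p)
        for pe in sorted(doc.peptide_evidences, key=lambda p: p.id):
            el = sub(seqc, "PeptideEvidence")
            el.set("id", pe.id)
            el.set("peptide_ref", pe.peptide_ref)
            el.set("dBSequence_ref", pe.db_sequence_ref)
            if pe.start is not None:
                el.set("start", str(pe.start))
            if pe.end is not None:
                el.set("end", str(pe.end))
            if pe.pre is not None:
                el.set("pre", pe.pre)
            if pe.post is not None:
                el.set("post", pe.post)
            el.set("isDecoy", _fmt_bool(pe.is_decoy))
            for p in pe.cv_params:
                _emit_param(el, p)

    anc = sub(root, "AnalysisCollection")
    for si in sorted(doc.spectrum_identifications, key=lambda s: s.id):
        el = sub(anc, "SpectrumIdentification")
        el.set("id", si.id)
        el.set("spectrumIdentificationProtocol_ref", si.protocol_ref)
        el.set("spectrumIdentificationList_ref", si.sil_ref)
        for ref in si.spectra_data_refs:
            sub(el, "InputSpectra").set("spectraData_ref", ref)
        for ref in si.search_database_refs:
            sub(el, "SearchDatabaseRef").set("searchDatabase_ref", ref)
    if doc.protein_detection is not None:
        pd = doc.protein_detection
        el = sub(anc, "ProteinDetection")
        el.set("id", pd.id)
        el.set("proteinDetectionProtocol_ref", pd.protocol_ref)
        el.set("proteinDetectionList_ref", pd.pdl_ref)
        for ref in pd.sil_refs:
            sub(el, "InputSpectrumIdentifications").set("spectrumIdentificationList_ref", ref)

    apc = sub(root, "AnalysisProtocolCollection")
    for prot in sorted(doc.protocols, key=lambda p: p.id):
        el = sub(apc, "SpectrumIdentificationProtocol")
        el.set("id", prot.id)
        el.set("analysisSoftware_ref", prot.software_ref)
        _emit_param(sub(el, "SearchType"), prot.search_type)
        if prot.additional_search_params:
            asp = sub(el, "AdditionalSearchParams")
            for p in prot.additional_search_params:
                _emit_param(asp, p)
        th = sub(el, "Threshold")
        for p in (prot.threshold or [m.CvParam("MS:1001494", "no threshold")]):
            _emit_param(th, p)
    if doc.protein_detection_protocol is not None:
        pdp = doc.protein_detection_protocol
        el = sub(apc, "ProteinDetectionProtocol")
        el.set("id", pdp.id)
        el.set("analysisSoftware_ref", pdp.software_ref)
        if pdp.analysis_params:
            ap = sub(el, "AnalysisParams")
            for p in pdp.analysis_params:
                _emit_param(ap, p)
        th = sub(el, "Threshold")
        for p in (pdp.threshold or [m.CvParam("MS:1001494", "no threshold")]):
            _emit_param(th, p)

    dc = sub(root, "DataCollection")
    inputs = sub(dc, "Inputs")
    for db in sorted(doc.search_databases, key=lambda d: d.id):
        el = sub(inputs, "SearchDatabase")
        el.set("id", db.id)
        el.set("location", db.location)
        _emit_param(sub(el, "DatabaseName"), db.database_name)
    for sd in sorted(doc.spectra_data, key=lambda s: s.id):
        el = sub(inputs, "SpectraData")
        el.set("id", sd.id)
        el.set("location", sd.location)
        _emit_param(sub(el, "FileFormat"), sd.file_format)
        _emit_param(sub(el, "SpectrumIDFormat"), sd.spectrum_id_format)
    adata = sub(dc, "AnalysisData")
    for sil in sorted(doc.spectrum_identification_lists, key=lambda s: s.id):
        sil_el = sub(adata, "SpectrumIdentificationList")
        sil_el.set("id", sil.id)
        for result in sorted(sil.results, key=lambda r: r.id):
            res_el = sub(sil_el, "SpectrumIdentificationResult")
            res_el.set("id", result.id)
            res_el.set("spectrumID", result.spectrum_id)
            res_el.set("spectraData_ref", result.spectra_data_ref)
            for item in sorted(result.items, key=lambda i: (i.rank, i.id)):
                it = sub(res_el, "SpectrumIdentificationItem")
                it.set("id", item.id)
                it.set("rank", str(item.rank))
                it.set("chargeState", str(item.charge_state))
                it.set("experimentalMassToCharge", _fmt_float(item.experimental_mz))
                if item.calculated_mz is not None:
                    it.set("calculatedMassToCharge", _fmt_float(item.calculated_mz))
                it.set("passThreshold", _fmt_bool(item.pass_threshold))
                it.set("peptide_ref", item.peptide_ref)
                for ref in item.peptide_evidence_refs:
                    sub(it, "PeptideEvidenceRef").set("peptideEvidence_ref", ref)
                for p in item.cv_params:
                    _emit_param(it, p)
            for p in result.cv_params:
                _emit_param(res_el, p)
    for pdl in doc.protein_detection_lists:
        pdl_el = sub(adata, "ProteinDetectionList")
        pdl_el.set("id", pdl.id)
        for group in sorted(pdl.groups, key=lambda g: g.id):
            g_el = sub(pdl_el, "ProteinAmbiguityGroup")
            g_el.set("id", group.id)
            for pdh in sorted(group.hypotheses, key=lambda h: h.id):
                h_el = sub(g_el, "ProteinDetectionHypothesis")
                h_el.set("id", pdh.id)
                h_el.set("dBSequence_ref", pdh.db_sequence_ref)
                h_el.set("passThreshold", _fmt_bool(pdh.pass_threshold))
                for ph in pdh.peptide_hypotheses:
                    ph_el = sub(h_el, "PeptideHypothesis")
                    ph_el.set("peptideEvidence_ref", ph.peptide_evidence_ref)
                    for ref in ph.sii_refs:
                        sub(ph_el, "SpectrumIdentificationItemRef").set(
                            "spectrumIdentificationItem_ref", ref)
                for p in pdh.cv_params:
                    _emit_param(h_el, p)
            for p in group.cv_params:
                _emit_param(g_el, p)
        for p in pdl.cv_params:
            _emit_param(pdl_el, p)

    # re-emit preserved unknown root children at their original positions
    for pos, blob in doc.extras:
        child = etree.fromstring(blob)
        root.insert(min(pos, len(root)), child)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---------------------------------------------------------------------------
# schema check
# ---------------------------------------------------------------------------

_schema_cache: dict[str, etree.XMLSchema] = {}


def _schema_for(series: str) -> etree.XMLSchema:
    if series not in _schema_cache:
        if series not in _SCHEMA_FILES:
            raise VersionError(f"no schema for version series {series!r}")
        text = (files("mzidkit") / "data" / _SCHEMA_FILES[series]).read_bytes()
        _schema_cache[series] = etree.XMLSchema(etree.fromstring(text))
    return _schema_cache[series]


def xsd_check(source: Source, version: str | None = None) -> list:
    """Validate against the vendored subset schema for the version series.

    Returns one error-level :class:`~mzidkit.validator.ValidationMessage`
    per violation (empty list = schema-valid).  Note the vendored schemas
    are subset schemas covering the elements this library emits.
    """
    from .validator import ValidationMessage  # local import avoids a cycle at startup

    data = _as_bytes(source)
    if version is None:
        version = detect_version(data)
    schema = _schema_for(_series(version))
    tree = etree.fromstring(data)
    if schema.validate(tree):
        return []
    return [
        ValidationMessage(
            rule_id="XSD",
            level="error",
            locus=f"line {entry.line}",
            text=entry.message,
        )
        for entry in schema.error_log
    ]
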
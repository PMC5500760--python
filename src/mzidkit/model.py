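"""In-memory object graph for mzIdentML documents.

The classes mirror the element structure shared by the 1.1 and 1.2
schemas: PSMs (``SpectrumIdentificationItem``) grouped per spectrum
(``SpectrumIdentificationResult``) inside one or more result lists,
re-usable ``Peptide`` objects, ``PeptideEvidence`` links from peptides to
database proteins (``DBSequence``), and an optional protein-inference
section (``ProteinDetectionList``).  Identifiers are opaque strings with
file-wide uniqueness, enforced at :meth:`Document.index` time rather than
per class, matching how the format defines them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import DanglingReferenceError, DuplicateIdError
from .terms import WORKFLOW_FLAGS

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CvParam:
    """A (accession, name, value) annotation sourced from a controlled vocabulary."""

    accession: str
    name: str
    value: Optional[str] = None
    cv_ref: str = "PSI-MS"
    unit_accession: Optional[str] = None
    unit_name: Optional[str] = None


@dataclass
class UserParam:
    """Free-text annotation outside any controlled vocabulary."""

    name: str
    value: Optional[str] = None


@dataclass
class Cv:
    id: str
    full_name: str
    uri: str
    version: Optional[str] = None


@dataclass
class AnalysisSoftware:
    id: str
    software_name: CvParam
    name: Optional[str] = None
    version: Optional[str] = None


@dataclass
class Modification:
    """A (possibly ambiguous) modification on a peptide.

    ``location`` is 1-based along the sequence with 0 meaning the
    N-terminus and len+1 the C-terminus.
    """

    location: int
    monoisotopic_mass_delta: float = 0.0
    residues: Optional[str] = None
    cv_params: list[CvParam] = field(default_factory=list)

    def param(self, accession: str) -> Optional[CvParam]:
        for p in self.cv_params:
            if isinstance(p, CvParam) and p.accession == accession:
                return p
        return None


@dataclass
class Peptide:
    id: str
    sequence: str = ""
    modifications: list[Modification] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)

    def modification_indices(self, index_accession: str) -> dict[int, Modification]:
        """Map declared modification-index values to their Modification."""
        out: dict[int, Modification] = {}
        for mod in self.modifications:
            p = mod.param(index_accession)
            if p is not None and p.value is not None:
                try:
                    out[int(p.value)] = mod
                except ValueError:
                    continue
        return out


@dataclass
class PeptideEvidence:
    id: str
    peptide_ref: str
    db_sequence_ref: str
    start: Optional[int] = None
    end: Optional[int] = None
    pre: Optional[str] = None
    post: Optional[str] = None
    is_decoy: bool = False
    cv_params: list[CvParam] = field(default_factory=list)

    def param(self, accession: str) -> Optional[CvParam]:
        for p in self.cv_params:
            if isinstance(p, CvParam) and p.accession == accession:
                return p
        return None


@dataclass
class DBSequence:
    id: str
    accession: str
    search_database_ref: str
    seq: Optional[str] = None
    cv_params: list[CvParam] = field(default_factory=list)

    def param(self, accession: str) -> Optional[CvParam]:
        for p in self.cv_params:
            if isinstance(p, CvParam) and p.accession == accession:
                return p
        return None


@dataclass
class SpectrumIdentificationItem:
    """One PSM: a candidate peptide explanation for one spectrum."""

    id: str
    rank: int
    charge_state: int
    experimental_mz: float
    peptide_ref: str
    pass_threshold: bool = True
    calculated_mz: Optional[float] = None
    peptide_evidence_refs: list[str] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)

    def param(self, accession: str) -> Optional[CvParam]:
        for p in self.cv_params:
            if isinstance(p, CvParam) and p.accession == accession:
                return p
        return None


@dataclass
class SpectrumIdentificationResult:
    """All reported identifications of a single searched spectrum."""

    id: str
    spectrum_id: str
    spectra_data_ref: str
    items: list[SpectrumIdentificationItem] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)


@dataclass
class SpectrumIdentificationList:
    id: str
    results: list[SpectrumIdentificationResult] = field(default_factory=list)


@dataclass
class SpectrumIdentificationProtocol:
    id: str
    software_ref: str
    search_type: CvParam = field(
        default_factory=lambda: CvParam("MS:1001083", "ms-ms search")
    )
    additional_search_params: list[CvParam | UserParam] = field(default_factory=list)
    threshold: list[CvParam | UserParam] = field(
        default_factory=lambda: [CvParam("MS:1001494", "no threshold")]
    )


@dataclass
class ProteinDetectionProtocol:
    id: str
    software_ref: str
    analysis_params: list[CvParam | UserParam] = field(default_factory=list)
    threshold: list[CvParam | UserParam] = field(
        default_factory=lambda: [CvParam("MS:1001494", "no threshold")]
    )


@dataclass
class PeptideHypothesis:
    peptide_evidence_ref: str
    sii_refs: list[str] = field(default_factory=list)


@dataclass
class ProteinDetectionHypothesis:
    """Evidence that a single database accession was identified."""

    id: str
    db_sequence_ref: str
    pass_threshold: bool = True
    peptide_hypotheses: list[PeptideHypothesis] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)


@dataclass
class ProteinAmbiguityGroup:
    """Proteins that the identified peptides cannot (fully) distinguish."""

    id: str
    hypotheses: list[ProteinDetectionHypothesis] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)


@dataclass
class ProteinDetectionList:
    id: str
    groups: list[ProteinAmbiguityGroup] = field(default_factory=list)
    cv_params: list[CvParam] = field(default_factory=list)


@dataclass
class SearchDatabase:
    id: str
    location: str
    database_name: CvParam | UserParam = field(
        default_factory=lambda: UserParam("database")
    )


@dataclass
class SpectraData:
    id: str
    location: str
    file_format: CvParam = field(
        default_factory=lambda: CvParam("MS:1001062", "Mascot MGF format")
    )
    spectrum_id_format: CvParam = field(
        default_factory=lambda: CvParam("MS:1000774", "multiple peak list nativeID format")
    )


@dataclass
class SpectrumIdentification:
    """AnalysisCollection entry tying inputs, protocol and result list together."""

    id: str
    protocol_ref: str
    sil_ref: str
    spectra_data_refs: list[str] = field(default_factory=list)
    search_database_refs: list[str] = field(default_factory=list)


@dataclass
class ProteinDetection:
    id: str
    protocol_ref: str
    pdl_ref: str
    sil_refs: list[str] = field(default_factory=list)


@dataclass
class Document:
    """A whole mzIdentML file as one object graph."""

    version: str = "1.2.0"
    cvs: list[Cv] = field(default_factory=list)
    analysis_software: list[AnalysisSoftware] = field(default_factory=list)
    db_sequences: list[DBSequence] = field(default_factory=list)
    peptides: list[Peptide] = field(default_factory=list)
    peptide_evidences: list[PeptideEvidence] = field(default_factory=list)
    spectrum_identifications: list[SpectrumIdentification] = field(default_factory=list)
    protein_detection: Optional[ProteinDetection] = None
    protocols: list[SpectrumIdentificationProtocol] = field(default_factory=list)
    protein_detection_protocol: Optional[ProteinDetectionProtocol] = None
    search_databases: list[SearchDatabase] = field(default_factory=list)
    spectra_data: list[SpectraData] = field(default_factory=list)
    spectrum_identification_lists: list[SpectrumIdentificationList] = field(default_factory=list)
    protein_detection_lists: list[ProteinDetectionList] = field(default_factory=list)
    #: unknown root-level children, preserved verbatim as (position, xml bytes)
    extras: list[tuple[int, bytes]] = field(default_factory=list)

    # -- id registry ------------------------------------------------------
    def _identified(self) -> Iterator[tuple[str, object]]:
        for coll in (
            self.analysis_software,
            self.db_sequences,
            self.peptides,
            self.peptide_evidences,
            self.spectrum_identifications,
            self.protocols,
            self.search_databases,
            self.spectra_data,
        ):
            for el in coll:
                yield el.id, el
        if self.protein_detection is not None:
            yield self.protein_detection.id, self.protein_detection
        if self.protein_detection_protocol is not None:
            yield self.protein_detection_protocol.id, self.protein_detection_protocol
        for sil in self.spectrum_identification_lists:
            yield sil.id, sil
            for result in sil.results:
                yield result.id, result
                for item in result.items:
                    yield item.id, item
        for pdl in self.protein_detection_lists:
            yield pdl.id, pdl
            for group in pdl.groups:
                yield group.id, group
                for pdh in group.hypotheses:
                    yield pdh.id, pdh

    def index(self) -> dict[str, object]:
        """File-wide id → element map; raises on duplicate identifiers."""
        out: dict[str, object] = {}
        for el_id, el in self._identified():
            if el_id in out:
                raise DuplicateIdError(f"identifier {el_id!r} registered twice")
            out[el_id] = el
        return out

    def resolve(self, el_id: str):
        """Return the unique element registered under *el_id*."""
        try:
            return self.index()[el_id]
        except KeyError:
            raise DanglingReferenceError(f"unknown identifier {el_id!r}") from None

    # -- invariants -------------------------------------------------------
    @property
    def protein_detection_list(self) -> Optional[ProteinDetectionList]:
        return self.protein_detection_lists[0] if self.protein_detection_lists else None

    def iter_items(self) -> Iterator[tuple[SpectrumIdentificationList,
                                           SpectrumIdentificationResult,
                                           SpectrumIdentificationItem]]:
        for sil in self.spectrum_identification_lists:
            for result in sil.results:
                for item in result.items:
                    yield sil, result, item

    def check_references(self) -> list[str]:
        """Return the list of dangling reference ids (empty = closed graph)."""
        ids = set(self.index())
        missing: list[str] = []

        def need(ref: Optional[str]) -> None:
            if ref is not None and ref not in ids:
                missing.append(ref)

        for pe in self.peptide_evidences:
            need(pe.peptide_ref)
            need(pe.db_sequence_ref)
        for dbs in self.db_sequences:
            need(dbs.search_database_ref)
        for prot in self.protocols:
            need(prot.software_ref)
        if self.protein_detection_protocol is not None:
            need(self.protein_detection_protocol.software_ref)
        for si in self.spectrum_identifications:
            need(si.protocol_ref)
            need(si.sil_ref)
            for r in si.spectra_data_refs:
                need(r)
            for r in si.search_database_refs:
                need(r)
        if self.protein_detection is not None:
            need(self.protein_detection.protocol_ref)
            need(self.protein_detection.pdl_ref)
            for r in self.protein_detection.sil_refs:
                need(r)
        for _sil, result, item in self.iter_items():
            need(result.spectra_data_ref)
            need(item.peptide_ref)
            for r in item.peptide_evidence_refs:
                need(r)
        for pdl in self.protein_detection_lists:
            for group in pdl.groups:
                for pdh in group.hypotheses:
                    need(pdh.db_sequence_ref)
                    for ph in pdh.peptide_hypotheses:
                        need(ph.peptide_evidence_ref)
                        for r in ph.sii_refs:
                            need(r)
        return missing

    def assert_closed(self) -> None:
        missing = self.check_references()
        if missing:
            raise DanglingReferenceError(
                "dangling references: " + ", ".join(sorted(set(missing)))
            )

    def is_v12(self) -> bool:
        return self.version.startswith("1.2")

    def workflow_flags(self) -> set[str]:
        """The Table-of-workflows flag accessions declared on any protocol."""
        flags: set[str] = set()
        for prot in self.protocols:
            for p in prot.additional_search_params:
                if isinstance(p, CvParam) and p.accession in WORKFLOW_FLAGS:
                    flags.add(p.accession)
        return flags


def workflow_flags(doc: Document) -> set[str]:
    """Module-level alias of :meth:`Document.workflow_flags`."""
    return doc.workflow_flags()
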
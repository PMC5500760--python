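"""Deterministic generator of valid mzIdentML fixtures, plus targeted corruption.

``generate`` builds, for any of the nine workflow flags, a document that is
schema-valid, semantically valid (zero error-level messages) and contains
that workflow's characteristic structures: indexed modifications and
four-field localization scores (including one '|'-ambiguous, one N-terminal
and one C-terminal case), donor/acceptor cross-link pairs with the
zero-mass acceptor convention, peptide groups with shared q-values,
genomic mappings with single-exon and junction-spanning evidence, and the
relaxed evidence cardinality of de novo / spectral-library results.

``corrupt`` plants exactly one seeded defect so that validation reports the
named rule and nothing else at error level — the other half of the
clean/defect test matrix.

Generation is a pure function of (workflow, parameters, seed): identical
inputs give byte-identical files.  Peptides are drawn from the 20-letter
amino-acid alphabet; decoys are sequence reversals flagged on their
evidence; target and decoy PSM scores come from two shifted Gaussians
(mean 100 vs 70, sd 10) so FDR curves are non-degenerate.
"""

from __future__ import annotations

import copy
import random

from . import model as m
from . import terms as t
from .errors import ParameterError
from .workflows import (
    GroupingMode,
    apply_peptide_annotations,
    group_psms,
    peptide_fdr,
)

WORKFLOWS: tuple[str, ...] = (
    t.NO_SPECIAL_PROCESSING,
    t.MODIFICATION_LOCALIZATION_SCORING,
    t.CROSS_LINKING_SEARCH,
    t.PEPTIDE_LEVEL_SCORING,
    t.CONSENSUS_SCORING,
    t.SAMPLE_PREFRACTIONATION,
    t.DE_NOVO_SEARCH,
    t.SPECTRAL_LIBRARY_SEARCH,
    t.PROTEOGENOMICS_SEARCH,
)

RULE_IDS: tuple[str, ...] = (
    "FLAG-1",
    "LOC-1", "LOC-2", "LOC-3", "LOC-4",
    "XL-1", "XL-2", "XL-3", "XL-4", "XL-5",
    "PEP-1", "PEP-2", "PEP-3", "PEP-4",
    "CARD-1", "UNIQ-1",
    "PG-1", "PG-2", "PG-3",
    "SPEC-1",
)

#: which generated workflow each defect is planted in
FIXTURE_FOR_DEFECT: dict[str, str] = {
    "FLAG-1": t.NO_SPECIAL_PROCESSING,
    "CARD-1": t.NO_SPECIAL_PROCESSING,
    "UNIQ-1": t.NO_SPECIAL_PROCESSING,
    "SPEC-1": t.NO_SPECIAL_PROCESSING,
    **{r: t.MODIFICATION_LOCALIZATION_SCORING
       for r in ("LOC-1", "LOC-2", "LOC-3", "LOC-4")},
    **{r: t.CROSS_LINKING_SEARCH
       for r in ("XL-1", "XL-2", "XL-3", "XL-4", "XL-5")},
    **{r: t.PEPTIDE_LEVEL_SCORING
       for r in ("PEP-1", "PEP-2", "PEP-3", "PEP-4")},
    **{r: t.PROTEOGENOMICS_SEARCH for r in ("PG-1", "PG-2", "PG-3")},
}

_PHOSPHO_MASS = 79.966331
_DSS_MASS = 138.06808
_REG = t.DEFAULT_REGISTRY


def _flag_param(flag: str) -> m.CvParam:
    return m.CvParam(flag, t.FLAG_NAMES[flag])


def _score_param(rng: random.Random, decoy: bool) -> m.CvParam:
    mean = 70.0 if decoy else 100.0
    return m.CvParam(t.MSGF_RAW_SCORE, "MS-GF:RawScore",
                     value=f"{rng.gauss(mean, 10.0):.4f}")


def _sequence(rng: random.Random, lo: int = 8, hi: int = 15) -> str:
    return "".join(rng.choice(m.AMINO_ACIDS)
                   for _ in range(rng.randint(lo, hi)))


class _Builder:
    """Accumulates the shared document skeleton for one fixture."""

    def __init__(self, flag: str, version: str, rng: random.Random):
        self.rng = rng
        self.doc = m.Document(version=version)
        self.doc.cvs = [
            m.Cv("PSI-MS",
                 "Proteomics Standards Initiative Mass Spectrometry Vocabularies",
                 "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
            m.Cv("UNIMOD", "UNIMOD", "http://www.unimod.org/obo/unimod.obo"),
        ]
        self.doc.analysis_software = [m.AnalysisSoftware(
            id="SW_1",
            software_name=m.CvParam("MS:1000799", "custom unreleased software tool",
                                    value="mzidkit-synth"),
            name="mzidkit-synth", version="1.0",
        )]
        self.doc.spectra_data = [m.SpectraData("SD_1", "file:///data/run1.mgf")]
        self.protocol = m.SpectrumIdentificationProtocol(
            id="SIP_1", software_ref="SW_1",
            additional_search_params=[_flag_param(flag)],
        )
        self.doc.protocols = [self.protocol]
        self.evidence_of: dict[str, list[str]] = {}  # peptide id -> PE ids
        self.sii_by_pe: dict[str, list[str]] = {}

    def add_search_database(self) -> None:
        self.doc.search_databases = [m.SearchDatabase(
            id="SDB_1", location="file:///db/target_decoy.fasta",
            database_name=m.CvParam("MS:1001013", "database name",
                                    value="target_decoy"),
        )]

    def add_protein(self, idx: int, decoy: bool) -> m.DBSequence:
        acc = f"{'DECOY_' if decoy else ''}PROT_{idx}"
        dbs = m.DBSequence(id=f"DBS_{idx}", accession=acc,
                           search_database_ref="SDB_1")
        self.doc.db_sequences.append(dbs)
        return dbs

    def add_peptide(self, idx: int, sequence: str,
                    mods: list[m.Modification] | None = None,
                    cv_params: list[m.CvParam] | None = None) -> m.Peptide:
        pep = m.Peptide(id=f"PEP_{idx}", sequence=sequence,
                        modifications=mods or [],
                        cv_params=cv_params or [])
        self.doc.peptides.append(pep)
        return pep

    def add_evidence(self, idx: int, pep: m.Peptide, dbs: m.DBSequence,
                     decoy: bool,
                     cv_params: list[m.CvParam] | None = None) -> m.PeptideEvidence:
        start = self.rng.randint(1, 300)
        pe = m.PeptideEvidence(
            id=f"PE_{idx}", peptide_ref=pep.id, db_sequence_ref=dbs.id,
            start=start, end=start + max(len(pep.sequence), 1) - 1,
            is_decoy=decoy, cv_params=cv_params or [],
        )
        self.doc.peptide_evidences.append(pe)
        self.evidence_of.setdefault(pep.id, []).append(pe.id)
        return pe

    def new_sil(self, idx: int = 1) -> m.SpectrumIdentificationList:
        sil = m.SpectrumIdentificationList(id=f"SIL_{idx}")
        self.doc.spectrum_identification_lists.append(sil)
        self.doc.spectrum_identifications.append(m.SpectrumIdentification(
            id=f"SI_{idx}", protocol_ref="SIP_1", sil_ref=sil.id,
            spectra_data_refs=["SD_1"],
            search_database_refs=(["SDB_1"] if self.doc.search_databases else []),
        ))
        return sil

    def add_psm(self, sil: m.SpectrumIdentificationList, spectrum_idx: int,
                pep: m.Peptide, decoy: bool,
                extra_params: list[m.CvParam] | None = None,
                ) -> m.SpectrumIdentificationItem:
        result = m.SpectrumIdentificationResult(
            id=f"SIR_{spectrum_idx}", spectrum_id=f"index={spectrum_idx}",
            spectra_data_ref="SD_1",
        )
        sil.results.append(result)
        item = m.SpectrumIdentificationItem(
            id=f"SII_{spectrum_idx}_1", rank=1,
            charge_state=self.rng.choice((2, 3)),
            experimental_mz=round(self.rng.uniform(400.0, 1200.0), 4),
            peptide_ref=pep.id,
            peptide_evidence_refs=list(self.evidence_of.get(pep.id, [])),
            cv_params=[_score_param(self.rng, decoy)] + (extra_params or []),
        )
        result.items.append(item)
        for pe_id in item.peptide_evidence_refs:
            self.sii_by_pe.setdefault(pe_id, []).append(item.id)
        return item

    def add_protein_detection(self) -> None:
        """One ambiguity group per database entry with referenced evidence."""
        pdl = m.ProteinDetectionList(id="PDL_1")
        n = 0
        for dbs in self.doc.db_sequences:
            hyps: list[m.PeptideHypothesis] = []
            for pe in self.doc.peptide_evidences:
                if pe.db_sequence_ref == dbs.id and pe.id in self.sii_by_pe:
                    hyps.append(m.PeptideHypothesis(
                        peptide_evidence_ref=pe.id,
                        sii_refs=list(self.sii_by_pe[pe.id]),
                    ))
            if not hyps:
                continue
            n += 1
            pdl.groups.append(m.ProteinAmbiguityGroup(
                id=f"PAG_{n}",
                hypotheses=[m.ProteinDetectionHypothesis(
                    id=f"PDH_{n}", db_sequence_ref=dbs.id,
                    pass_threshold=True, peptide_hypotheses=hyps,
                )],
            ))
        self.doc.protein_detection_lists = [pdl]
        self.doc.protein_detection_protocol = m.ProteinDetectionProtocol(
            id="PDP_1", software_ref="SW_1")
        self.doc.protein_detection = m.ProteinDetection(
            id="PD_1", protocol_ref="PDP_1", pdl_ref="PDL_1",
            sil_refs=[sil.id for sil in self.doc.spectrum_identification_lists],
        )


def _standard_peptide_set(b: _Builder, n_peptides: int, decoy_fraction: float,
                          ) -> list[tuple[m.Peptide, bool]]:
    """Targets plus reversed-sequence decoys, each with protein + evidence."""
    n_decoy = max(1, round(n_peptides * decoy_fraction))
    pool: list[tuple[m.Peptide, bool]] = []
    for i in range(n_peptides):
        seq = _sequence(b.rng)
        pep = b.add_peptide(i + 1, seq)
        dbs = b.add_protein(i + 1, decoy=False)
        b.add_evidence(i + 1, pep, dbs, decoy=False)
        pool.append((pep, False))
    for j in range(n_decoy):
        src = pool[j][0].sequence[::-1]
        idx = n_peptides + j + 1
        pep = b.add_peptide(idx, src)
        dbs = b.add_protein(idx, decoy=True)
        b.add_evidence(idx, pep, dbs, decoy=True)
        pool.append((pep, True))
    return pool


def generate(workflow: str, n_spectra: int = 20, n_peptides: int = 12,
             decoy_fraction: float = 0.3, seed: int = 1,
             version: str = "1.2.0",
             grouping_mode: GroupingMode = GroupingMode.SEQUENCE,
             fdr_threshold: float = 0.01) -> m.Document:
    """Build a valid fixture document for one of the nine workflow flags."""
    if workflow not in WORKFLOWS:
        raise ParameterError(f"unknown workflow flag {workflow!r}")
    if n_spectra < 1 or n_peptides < 2:
        raise ParameterError("need n_spectra >= 1 and n_peptides >= 2")
    rng = random.Random(f"{workflow}|{n_spectra}|{n_peptides}|"
                        f"{decoy_fraction}|{seed}|{version}")
    b = _Builder(workflow, version, rng)

    if workflow == t.CROSS_LINKING_SEARCH:
        _fill_crosslink(b, n_spectra)
    elif workflow == t.MODIFICATION_LOCALIZATION_SCORING:
        _fill_localization(b, n_spectra, n_peptides, decoy_fraction)
    elif workflow == t.PEPTIDE_LEVEL_SCORING:
        _fill_peptide_level(b, n_spectra, n_peptides, decoy_fraction,
                            grouping_mode, fdr_threshold)
    elif workflow == t.DE_NOVO_SEARCH:
        _fill_db_free(b, n_spectra, n_peptides, library=False)
    elif workflow == t.SPECTRAL_LIBRARY_SEARCH:
        _fill_db_free(b, n_spectra, n_peptides, library=True)
    elif workflow == t.PROTEOGENOMICS_SEARCH:
        _fill_proteogenomics(b, n_spectra, n_peptides, decoy_fraction)
    elif workflow == t.SAMPLE_PREFRACTIONATION:
        _fill_prefractionation(b, n_spectra, n_peptides, decoy_fraction)
    else:  # no special processing / consensus
        b.add_search_database()
        pool = _standard_peptide_set(b, n_peptides, decoy_fraction)
        sil = b.new_sil()
        if workflow == t.CONSENSUS_SCORING:
            b.doc.analysis_software.append(m.AnalysisSoftware(
                id="SW_2",
                software_name=m.CvParam("MS:1000799",
                                        "custom unreleased software tool",
                                        value="second-engine"),
            ))
        for i in range(n_spectra):
            pep, decoy = rng.choice(pool)
            extra = []
            if workflow == t.CONSENSUS_SCORING:
                extra.append(m.CvParam(
                    "MS:1002053", "MS-GF:EValue",
                    value=f"{rng.uniform(1e-12, 1e-3):.3e}"))
            b.add_psm(sil, i, pep, decoy, extra_params=extra)

    doc = b.doc
    doc.index()
    doc.assert_closed()
    return doc


# -- per-workflow fillers ----------------------------------------------------

def _fill_localization(b: _Builder, n_spectra: int, n_peptides: int,
                       decoy_fraction: float) -> None:
    b.add_search_database()
    rng = b.rng
    pool: list[tuple[m.Peptide, bool]] = []
    n_decoy = max(1, round(n_peptides * decoy_fraction))
    for i in range(n_peptides + n_decoy):
        decoy = i >= n_peptides
        seq = _sequence(rng, 10, 15)
        n_mods = 2 if i == 0 else rng.randint(1, 2)
        locations = rng.sample(range(1, len(seq) + 1), n_mods)
        mods = [
            m.Modification(
                location=loc,
                monoisotopic_mass_delta=_PHOSPHO_MASS,
                residues=seq[loc - 1],
                cv_params=[
                    m.CvParam("UNIMOD:21", "Phospho", cv_ref="UNIMOD"),
                    m.CvParam(_REG.modification_index, "modification index",
                              value=str(k + 1)),
                ],
            )
            for k, loc in enumerate(sorted(locations))
        ]
        pep = b.add_peptide(i + 1, seq, mods=mods)
        dbs = b.add_protein(i + 1, decoy=decoy)
        b.add_evidence(i + 1, pep, dbs, decoy=decoy)
        pool.append((pep, decoy))
    b.protocol.threshold = [m.CvParam("MS:1002546", "localization site probability",
                                      value="0.75")]
    sil = b.new_sil()
    for i in range(n_spectra):
        pep, decoy = rng.choice(pool)
        length = len(pep.sequence)
        params: list[m.CvParam] = []
        for k, mod in enumerate(pep.modifications):
            idx = k + 1
            score = rng.uniform(10.0, 99.0)
            if i == 0 and k == 0:
                # ambiguous site: logical-OR positions, never a confident site
                pos_a = min(mod.location, length - 1)
                positions = f"{pos_a}|{pos_a + 1}"
                passed = True
            elif i == 1 and k == 0:
                positions, passed = "0", True          # N-terminus
            elif i == 2 and k == 0:
                positions, passed = str(length + 1), True  # C-terminus
            else:
                positions = str(mod.location)
                passed = score >= 75.0
            params.append(m.CvParam(
                "MS:1002546", "localization site probability",
                value=f"{idx}:{score:.2f}:{positions}:"
                      f"{'true' if passed else 'false'}",
            ))
        b.add_psm(sil, i, pep, decoy, extra_params=params)


def _fill_crosslink(b: _Builder, n_spectra: int) -> None:
    b.add_search_database()
    b.doc.cvs.append(m.Cv("XLMOD", "cross-linker CV",
                          "https://raw.githubusercontent.com/HUPO-PSI/mzIdentML/master/cv/XLMOD.obo"))
    rng = b.rng
    sil = b.new_sil()
    for i in range(n_spectra):
        donor_seq = _sequence(rng, 10, 14)
        acceptor_seq = _sequence(rng, 8, 9)
        link = f"XL{i + 1}"
        donor = b.add_peptide(2 * i + 1, donor_seq, mods=[m.Modification(
            location=rng.randint(1, len(donor_seq)),
            monoisotopic_mass_delta=_DSS_MASS,
            residues="K",
            cv_params=[
                m.CvParam("XLMOD:02001", "DSS", cv_ref="XLMOD"),
                m.CvParam(_REG.cross_link_donor, "cross-link donor", value=link),
            ],
        )])
        acceptor = b.add_peptide(2 * i + 2, acceptor_seq, mods=[m.Modification(
            location=rng.randint(1, len(acceptor_seq)),
            monoisotopic_mass_delta=0.0,
            residues="K",
            cv_params=[
                m.CvParam(_REG.cross_link_acceptor, "cross-link acceptor",
                          value=link),
            ],
        )])
        dbs_d = b.add_protein(2 * i + 1, decoy=False)
        dbs_a = b.add_protein(2 * i + 2, decoy=False)
        b.add_evidence(2 * i + 1, donor, dbs_d, decoy=False)
        b.add_evidence(2 * i + 2, acceptor, dbs_a, decoy=False)

        result = m.SpectrumIdentificationResult(
            id=f"SIR_{i}", spectrum_id=f"index={i}", spectra_data_ref="SD_1")
        sil.results.append(result)
        shared_score = m.CvParam(t.MSGF_RAW_SCORE, "MS-GF:RawScore",
                                 value=f"{rng.gauss(100.0, 10.0):.4f}")
        pairing = str(i + 1)
        for j, pep in enumerate((donor, acceptor), start=1):
            result.items.append(m.SpectrumIdentificationItem(
                id=f"SII_{i}_{j}", rank=1,
                charge_state=rng.choice((3, 4)),
                experimental_mz=round(rng.uniform(500.0, 1400.0), 4),
                peptide_ref=pep.id,
                peptide_evidence_refs=list(b.evidence_of[pep.id]),
                cv_params=[
                    m.CvParam(shared_score.accession, shared_score.name,
                              value=shared_score.value),
                    m.CvParam(_REG.cross_link_sii,
                              "cross-link spectrum identification item",
                              value=pairing),
                ],
            ))


def _fill_peptide_level(b: _Builder, n_spectra: int, n_peptides: int,
                        decoy_fraction: float, mode: GroupingMode,
                        fdr_threshold: float) -> None:
    b.add_search_database()
    rng = b.rng
    pool = _standard_peptide_set(b, n_peptides, decoy_fraction)
    # phospho variants of some targets: same sequence, distinct modification
    # state, so the three grouping modes genuinely differ
    variants: list[tuple[m.Peptide, bool]] = []
    for i, (pep, decoy) in enumerate(pool[:max(2, n_peptides // 3)]):
        if decoy:
            continue
        idx = len(b.doc.peptides) + 1
        mod_loc = rng.randint(1, len(pep.sequence))
        variant = b.add_peptide(idx, pep.sequence, mods=[m.Modification(
            location=mod_loc, monoisotopic_mass_delta=_PHOSPHO_MASS,
            residues=pep.sequence[mod_loc - 1],
            cv_params=[m.CvParam("UNIMOD:21", "Phospho", cv_ref="UNIMOD")],
        )])
        dbs = b.doc.db_sequences[i]
        b.add_evidence(idx, variant, dbs, decoy=False)
        variants.append((variant, False))
    pool = pool + variants
    sil = b.new_sil()
    for i in range(n_spectra):
        pep, decoy = rng.choice(pool)
        b.add_psm(sil, i, pep, decoy)
    groups = peptide_fdr(group_psms(sil, b.doc, mode), higher_is_better=True)
    apply_peptide_annotations(b.doc, groups, threshold=fdr_threshold)


def _fill_db_free(b: _Builder, n_spectra: int, n_peptides: int,
                  library: bool) -> None:
    """De novo / spectral-library results: no peptide-to-protein evidence."""
    rng = b.rng
    pool: list[m.Peptide] = []
    for i in range(n_peptides):
        params = []
        if library:
            params.append(m.CvParam("MS:1002551", "spectral library entry confidence",
                                    value=f"{rng.uniform(0.5, 1.0):.3f}"))
        pool.append(b.add_peptide(i + 1, _sequence(rng), cv_params=params))
    if library:
        # a library entry identified with no known peptide sequence
        pool.append(b.add_peptide(
            n_peptides + 1, "",
            cv_params=[m.CvParam("MS:1002551", "spectral library entry confidence",
                                 value="0.990")]))
    sil = b.new_sil()
    for i in range(n_spectra):
        b.add_psm(sil, i, rng.choice(pool), decoy=False)


def _fill_proteogenomics(b: _Builder, n_spectra: int, n_peptides: int,
                         decoy_fraction: float) -> None:
    b.add_search_database()
    rng = b.rng
    n_decoy = max(1, round(n_peptides * decoy_fraction))
    pool: list[tuple[m.Peptide, bool]] = []
    for i in range(n_peptides + n_decoy):
        decoy = i >= n_peptides
        seq = _sequence(rng, 8, 12)
        pep = b.add_peptide(i + 1, seq)
        dbs = b.add_protein(i + 1, decoy=decoy)
        dbs.cv_params.extend([
            m.CvParam(_REG.pg_genome_build, "genome reference version",
                      value="GRCh38"),
            m.CvParam(_REG.pg_chromosome, "chromosome name",
                      value=f"chr{rng.randint(1, 22)}"),
            m.CvParam(_REG.pg_strand, "chromosome strand",
                      value=rng.choice("+-")),
        ])
        coding = 3 * len(seq)
        g = rng.randint(10_000, 5_000_000)
        if i % 3 == 1:  # junction-spanning: two exon blocks
            first = rng.randint(3, coding - 3)
            intron = rng.randint(100, 5_000)
            starts = [g, g + first + intron]
            ends = [g + first - 1, g + first + intron + (coding - first) - 1]
        else:           # single exon
            starts, ends = [g], [g + coding - 1]
        b.add_evidence(i + 1, pep, dbs, decoy=decoy, cv_params=[
            m.CvParam(_REG.pg_start_positions,
                      "peptide start positions on chromosome",
                      value=",".join(map(str, starts))),
            m.CvParam(_REG.pg_end_positions,
                      "peptide end positions on chromosome",
                      value=",".join(map(str, ends))),
            m.CvParam(_REG.pg_exon_count, "peptide exon count",
                      value=str(len(starts))),
        ])
        pool.append((pep, decoy))
    sil = b.new_sil()
    for i in range(n_spectra):
        pep, decoy = rng.choice(pool)
        b.add_psm(sil, i, pep, decoy)


def _fill_prefractionation(b: _Builder, n_spectra: int, n_peptides: int,
                           decoy_fraction: float) -> None:
    """n fractions searched separately, one merged protein list."""
    b.add_search_database()
    rng = b.rng
    pool = _standard_peptide_set(b, n_peptides, decoy_fraction)
    n_fractions = 3
    spectrum = 0
    per = max(1, (n_spectra + n_fractions - 1) // n_fractions)
    for f in range(1, n_fractions + 1):
        sil = b.new_sil(f)
        for _ in range(per):
            pep, decoy = rng.choice(pool)
            b.add_psm(sil, spectrum, pep, decoy)
            spectrum += 1
    b.add_protein_detection()


# ---------------------------------------------------------------------------
# targeted corruption
# ---------------------------------------------------------------------------

def corrupt(doc: m.Document, defect: str, seed: int = 0) -> m.Document:
    """Return a copy of *doc* violating exactly the named validator rule."""
    if defect not in RULE_IDS:
        raise ParameterError(f"unknown defect {defect!r}")
    doc = copy.deepcopy(doc)
    flags = doc.workflow_flags()

    def first_item() -> m.SpectrumIdentificationItem:
        for _sil, _res, item in doc.iter_items():
            return item
        raise ParameterError("document has no PSMs")

    if defect == "FLAG-1":
        for prot in doc.protocols:
            prot.additional_search_params = [
                p for p in prot.additional_search_params
                if not (isinstance(p, m.CvParam) and p.accession in t.WORKFLOW_FLAGS)
            ]
        if doc.workflow_flags():
            raise ParameterError("could not strip workflow flags")
        return doc

    if defect.startswith("LOC-"):
        if t.MODIFICATION_LOCALIZATION_SCORING not in flags:
            raise ParameterError(f"{defect} needs a localization fixture")
        return _corrupt_loc(doc, defect)
    if defect.startswith("XL-"):
        if t.CROSS_LINKING_SEARCH not in flags:
            raise ParameterError(f"{defect} needs a cross-linking fixture")
        return _corrupt_xl(doc, defect)
    if defect.startswith("PEP-"):
        if t.PEPTIDE_LEVEL_SCORING not in flags:
            raise ParameterError(f"{defect} needs a peptide-level fixture")
        return _corrupt_pep(doc, defect)
    if defect.startswith("PG-"):
        if t.PROTEOGENOMICS_SEARCH not in flags:
            raise ParameterError(f"{defect} needs a proteogenomics fixture")
        return _corrupt_pg(doc, defect)

    if defect == "CARD-1":
        if flags & {t.DE_NOVO_SEARCH, t.SPECTRAL_LIBRARY_SEARCH}:
            raise ParameterError("CARD-1 needs a database-search fixture")
        first_item().peptide_evidence_refs = []
        return doc
    if defect == "UNIQ-1":
        results = [res for sil in doc.spectrum_identification_lists
                   for res in sil.results]
        if len(results) < 2:
            raise ParameterError("UNIQ-1 needs at least two results")
        results[1].spectrum_id = results[0].spectrum_id
        results[1].spectra_data_ref = results[0].spectra_data_ref
        return doc
    if defect == "SPEC-1":
        if t.SPECTRAL_LIBRARY_SEARCH in flags:
            raise ParameterError("SPEC-1 needs a fixture without the library flag")
        if not doc.peptides:
            raise ParameterError("document has no peptides")
        doc.peptides[0].sequence = ""
        return doc
    raise ParameterError(f"unhandled defect {defect!r}")


def _loc_params(doc: m.Document):
    for _sil, _res, item in doc.iter_items():
        for p in item.cv_params:
            if isinstance(p, m.CvParam) and p.accession == "MS:1002546":
                yield item, p


def _corrupt_loc(doc: m.Document, defect: str) -> m.Document:
    if defect == "LOC-1":
        for pep in doc.peptides:
            if pep.modifications:
                mod = pep.modifications[0]
                existing = mod.param(_REG.modification_index)
                # a second index term where exactly one is allowed
                mod.cv_params.append(m.CvParam(
                    _REG.modification_index, "modification index",
                    value=existing.value))
                return doc
        raise ParameterError("no modified peptide found")
    index = doc.index()
    for item, p in _loc_params(doc):
        pep = index[item.peptide_ref]
        if defect == "LOC-2":
            p.value = "1:45.3:4"  # three fields
        elif defect == "LOC-3":
            p.value = "9:45.3:4:true"  # index 9 never declared
        else:  # LOC-4
            p.value = f"1:45.3:{len(pep.sequence) + 5}:true"
        return doc
    raise ParameterError("no localization score params found")


def _corrupt_xl(doc: m.Document, defect: str) -> m.Document:
    if defect == "XL-1":
        for pep in doc.peptides:
            for mod in pep.modifications:
                d = mod.param(_REG.cross_link_donor)
                if d is not None:
                    mod.cv_params.remove(d)
                    return doc
        raise ParameterError("no donor modification found")
    if defect == "XL-2":
        for pep in doc.peptides:
            for mod in pep.modifications:
                if mod.param(_REG.cross_link_acceptor) is not None:
                    mod.monoisotopic_mass_delta = 156.0786
                    return doc
        raise ParameterError("no acceptor modification found")
    for sil in doc.spectrum_identification_lists:
        for result in sil.results:
            if len(result.items) < 2:
                continue
            if defect == "XL-3":
                result.items[1].rank = 2
            elif defect == "XL-4":
                p = result.items[1].param(t.MSGF_RAW_SCORE)
                p.value = f"{float(p.value) + 1.0:.4f}"
            else:  # XL-5: drop one chain, leaving the pairing value unpaired
                del result.items[1]
            return doc
    raise ParameterError("no paired result found")


def _corrupt_pep(doc: m.Document, defect: str) -> m.Document:
    by_group: dict[str, list[m.SpectrumIdentificationItem]] = {}
    for _sil, _res, item in doc.iter_items():
        p = item.param(_REG.peptide_group_id)
        if p is not None:
            by_group.setdefault(p.value or "", []).append(item)
    if defect == "PEP-1":
        item = next(iter(doc.iter_items()))[2]
        item.cv_params.remove(item.param(_REG.peptide_group_id))
        return doc
    if defect == "PEP-2":
        for prot in doc.protocols:
            prot.additional_search_params = [
                p for p in prot.additional_search_params
                if not (isinstance(p, m.CvParam)
                        and p.accession in _REG.grouping_modes)
            ]
        return doc
    if defect == "PEP-3":
        for group_id in sorted(by_group):
            members = by_group[group_id]
            if len(members) >= 2:
                members[1].param(_REG.peptide_qvalue).value = "0.987654"
                return doc
        raise ParameterError("no peptide group with two PSMs")
    # PEP-4: move one PSM into a foreign group, keeping scores consistent so
    # only the recomputed-key consistency check (a warning) trips
    group_ids = sorted(by_group)
    if len(group_ids) < 2:
        raise ParameterError("need at least two peptide groups")
    target_id, source_id = group_ids[0], group_ids[1]
    moved = by_group[source_id][0]
    moved.param(_REG.peptide_group_id).value = target_id
    ref_q = by_group[target_id][0].param(_REG.peptide_qvalue)
    moved.param(_REG.peptide_qvalue).value = ref_q.value
    return doc


def _corrupt_pg(doc: m.Document, defect: str) -> m.Document:
    for pe in doc.peptide_evidences:
        starts = pe.param(_REG.pg_start_positions)
        if starts is None:
            continue
        if defect == "PG-1":
            pe.cv_params.remove(starts)
            return doc
        if defect == "PG-2":
            index = doc.index()
            dbs = index[pe.db_sequence_ref]
            strand = dbs.param(_REG.pg_strand)
            dbs.cv_params.remove(strand)
            return doc
        # PG-3: declared exon count disagrees with the block count
        exon = pe.param(_REG.pg_exon_count)
        exon.value = str(len((starts.value or "").split(",")) + 1)
        return doc
    raise ParameterError("no genomic coordinate params found")
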
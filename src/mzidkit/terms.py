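"""Well-known accessions and the configurable term registry.

mzIdentML 1.2 signals each analysis workflow by a protocol-level "flag"
term; downstream encodings (modification indices, cross-link pairing,
peptide grouping, genomic coordinates) hang off further terms.  Accessions
that the format documentation does not pin down (score branch roots, the
proteogenomics coordinate params) are registry attributes so deployments
using the full PSI-MS CV can remap them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# --- the nine protocol workflow flags -----------------------------------
PEPTIDE_LEVEL_SCORING = "MS:1002490"
MODIFICATION_LOCALIZATION_SCORING = "MS:1002491"
CONSENSUS_SCORING = "MS:1002492"
SAMPLE_PREFRACTIONATION = "MS:1002493"
CROSS_LINKING_SEARCH = "MS:1002494"
DE_NOVO_SEARCH = "MS:1001010"
PROTEOGENOMICS_SEARCH = "MS:1002635"
SPECTRAL_LIBRARY_SEARCH = "MS:1001031"
NO_SPECIAL_PROCESSING = "MS:1002495"

WORKFLOW_FLAGS: frozenset[str] = frozenset({
    PEPTIDE_LEVEL_SCORING,
    MODIFICATION_LOCALIZATION_SCORING,
    CONSENSUS_SCORING,
    SAMPLE_PREFRACTIONATION,
    CROSS_LINKING_SEARCH,
    DE_NOVO_SEARCH,
    PROTEOGENOMICS_SEARCH,
    SPECTRAL_LIBRARY_SEARCH,
    NO_SPECIAL_PROCESSING,
})

#: human-readable workflow names, for `describe` output
FLAG_NAMES: dict[str, str] = {
    PEPTIDE_LEVEL_SCORING: "Peptide-level scoring",
    MODIFICATION_LOCALIZATION_SCORING: "Modification localization scoring",
    CONSENSUS_SCORING: "Consensus scoring",
    SAMPLE_PREFRACTIONATION: "Sample pre-fractionation",
    CROSS_LINKING_SEARCH: "Cross-linking search",
    DE_NOVO_SEARCH: "De novo search",
    PROTEOGENOMICS_SEARCH: "Proteogenomics search",
    SPECTRAL_LIBRARY_SEARCH: "Spectral library search",
    NO_SPECIAL_PROCESSING: "No special processing",
}

# --- localization / cross-linking / grouping ----------------------------
MODIFICATION_INDEX = "MS:1002504"
CROSS_LINK_DONOR = "MS:1002509"
CROSS_LINK_ACCEPTOR = "MS:1002510"
CROSS_LINK_SII = "MS:1002511"
PEPTIDE_GROUP_ID = "MS:1002520"

GROUP_BY_SEQUENCE = "MS:1002496"
GROUP_BY_SEQUENCE_MODS = "MS:1002497"
GROUP_BY_SEQUENCE_MODS_CHARGE = "MS:1002498"
GROUPING_MODES: frozenset[str] = frozenset({
    GROUP_BY_SEQUENCE, GROUP_BY_SEQUENCE_MODS, GROUP_BY_SEQUENCE_MODS_CHARGE,
})

PEPTIDE_QVALUE = "MS:1001868"
MSGF_RAW_SCORE = "MS:1002049"


@dataclass(frozen=True)
class TermRegistry:
    """Accession bindings the validator and workflow helpers operate on.

    Branch roots identify score families in the active CV graph; the
    proteogenomics params name where genomic coordinates live on
    PeptideEvidence / DBSequence elements.
    """

    psm_score_root: str = "MS:1001143"
    peptide_score_root: str = "MS:1002358"
    localization_score_root: str = "MS:1002545"
    modification_index: str = MODIFICATION_INDEX
    cross_link_donor: str = CROSS_LINK_DONOR
    cross_link_acceptor: str = CROSS_LINK_ACCEPTOR
    cross_link_sii: str = CROSS_LINK_SII
    peptide_group_id: str = PEPTIDE_GROUP_ID
    grouping_modes: frozenset[str] = GROUPING_MODES
    peptide_qvalue: str = PEPTIDE_QVALUE
    # proteogenomics: PeptideEvidence-level coordinate params
    pg_start_positions: str = "MS:1002640"
    pg_end_positions: str = "MS:1002641"
    pg_exon_count: str = "MS:1002642"
    # proteogenomics: DBSequence-level gene-model params
    pg_genome_build: str = "MS:1002644"
    pg_chromosome: str = "MS:1002637"
    pg_strand: str = "MS:1002638"

    @property
    def pg_evidence_params(self) -> tuple[str, str, str]:
        return (self.pg_start_positions, self.pg_end_positions, self.pg_exon_count)

    @property
    def pg_dbsequence_params(self) -> tuple[str, str, str]:
        return (self.pg_genome_build, self.pg_chromosome, self.pg_strand)


DEFAULT_REGISTRY = TermRegistry()
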
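"""Computational helpers over the mzIdentML 1.2 workflow encodings.

Four feature families live here:

* the modification-localization score codec
  (``MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD`` values attached to PSMs)
  and the extraction of unambiguously localized protein sites;
* resolution of cross-linked peptide pairs from tied-rank PSM couples
  sharing a pairing identifier;
* PSM → peptide grouping under the three standard grouping keys, with
  target–decoy q-value estimation at the peptide level;
* decoding of peptide-to-genome coordinate annotations and BED12 export.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import model as m
from .cv import CvGraph, load_default_cv
from .errors import (
    AnnotationError,
    CrossLinkError,
    MappingError,
    ScoreGrammarError,
    ScoreRangeError,
    ScoreReferenceError,
)
from .terms import (
    DEFAULT_REGISTRY,
    GROUP_BY_SEQUENCE,
    GROUP_BY_SEQUENCE_MODS,
    GROUP_BY_SEQUENCE_MODS_CHARGE,
    MSGF_RAW_SCORE,
    PEPTIDE_LEVEL_SCORING,
    TermRegistry,
)


@lru_cache(maxsize=1)
def _default_cv() -> CvGraph:
    return load_default_cv()


# ---------------------------------------------------------------------------
# modification localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalizationScore:
    """One decoded modification-position score.

    ``positions`` are peptide coordinates: 0 is the N-terminus and
    ``len(sequence) + 1`` the C-terminus.  Multiple positions encode a
    logical OR — the score could not distinguish them.
    """

    term_accession: str
    mod_index: int
    score: float
    positions: tuple[int, ...]
    pass_threshold: bool

    @property
    def ambiguous(self) -> bool:
        return len(self.positions) > 1


def parse_localization_score(param: m.CvParam, peptide: m.Peptide,
                             registry: TermRegistry = DEFAULT_REGISTRY) -> LocalizationScore:
    """Decode a four-field localization score attached to a PSM.

    The value grammar is ``MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD`` with
    ``POSITION`` optionally '|'-joined over indistinguishable sites.
    """
    value = param.value or ""
    fields = value.split(":")
    if len(fields) != 4:
        raise ScoreGrammarError(
            f"expected 4 colon-separated fields, got {len(fields)} in {value!r}"
        )
    raw_index, raw_score, raw_pos, raw_pass = fields
    try:
        mod_index = int(raw_index)
    except ValueError:
        raise ScoreGrammarError(f"non-integer MOD_INDEX {raw_index!r}") from None
    try:
        score = float(raw_score)
    except ValueError:
        raise ScoreGrammarError(f"non-numeric SCORE {raw_score!r}") from None
    try:
        positions = sorted({int(p) for p in raw_pos.split("|")})
    except ValueError:
        raise ScoreGrammarError(f"non-integer POSITION in {raw_pos!r}") from None
    if len(positions) != len(raw_pos.split("|")):
        raise ScoreGrammarError(f"duplicate POSITION in {raw_pos!r}")
    if raw_pass.lower() not in ("true", "false"):
        raise ScoreGrammarError(f"PASS_THRESHOLD must be true/false, got {raw_pass!r}")

    if mod_index not in peptide.modification_indices(registry.modification_index):
        raise ScoreReferenceError(
            f"MOD_INDEX {mod_index} not declared on peptide {peptide.id!r}"
        )
    upper = len(peptide.sequence) + 1
    for p in positions:
        if not 0 <= p <= upper:
            raise ScoreRangeError(
                f"position {p} outside [0, {upper}] on peptide {peptide.id!r}"
            )
    return LocalizationScore(
        term_accession=param.accession,
        mod_index=mod_index,
        score=score,
        positions=tuple(positions),
        pass_threshold=raw_pass.lower() == "true",
    )


def emit_localization_score(ls: LocalizationScore, name: str | None = None) -> m.CvParam:
    """Inverse of :func:`parse_localization_score` (codec round trip)."""
    if not ls.positions:
        raise ScoreGrammarError("a localization score needs at least one position")
    if list(ls.positions) != sorted(set(ls.positions)):
        raise ScoreGrammarError("positions must be sorted and unique")
    value = ":".join([
        str(ls.mod_index),
        repr(float(ls.score)),
        "|".join(str(p) for p in ls.positions),
        "true" if ls.pass_threshold else "false",
    ])
    return m.CvParam(accession=ls.term_accession,
                     name=name or ls.term_accession, value=value)


def localization_score_terms(cv: CvGraph | None = None,
                             registry: TermRegistry = DEFAULT_REGISTRY) -> set[str]:
    cv = cv or _default_cv()
    return cv.descendants(registry.localization_score_root)


def confident_sites(doc: m.Document, cv: CvGraph | None = None,
                    registry: TermRegistry = DEFAULT_REGISTRY,
                    ) -> list[tuple[str, int, str, float]]:
    """Protein sites whose modification position passed threshold unambiguously.

    Returns ``(protein accession, protein position, modification accession,
    score)`` tuples, deduplicated on the first three fields keeping the best
    (highest) score.  Ambiguous ('|') positions never contribute, whatever
    their threshold status; peptide position p maps to protein position
    ``PeptideEvidence.start + p - 1``.
    """
    loc_terms = localization_score_terms(cv, registry)
    index = doc.index()
    best: dict[tuple[str, int, str], float] = {}
    for _sil, _res, item in doc.iter_items():
        peptide = index.get(item.peptide_ref)
        if not isinstance(peptide, m.Peptide):
            continue
        mods = peptide.modification_indices(registry.modification_index)
        for param in item.cv_params:
            if not isinstance(param, m.CvParam) or param.accession not in loc_terms:
                continue
            ls = parse_localization_score(param, peptide, registry)
            if not ls.pass_threshold or ls.ambiguous:
                continue
            mod = mods[ls.mod_index]
            mod_acc = _modification_identity(mod, registry)
            for ref in item.peptide_evidence_refs:
                pe = index.get(ref)
                if not isinstance(pe, m.PeptideEvidence):
                    continue
                if pe.start is None:
                    warnings.warn(
                        f"PeptideEvidence {pe.id} lacks a start position; site skipped",
                        stacklevel=2,
                    )
                    continue
                dbs = index.get(pe.db_sequence_ref)
                acc = dbs.accession if isinstance(dbs, m.DBSequence) else pe.db_sequence_ref
                key = (acc, pe.start + ls.positions[0] - 1, mod_acc)
                if key not in best or ls.score > best[key]:
                    best[key] = ls.score
    return sorted((k[0], k[1], k[2], v) for k, v in best.items())


def _modification_identity(mod: m.Modification, registry: TermRegistry) -> str:
    skip = {registry.modification_index, registry.cross_link_donor,
            registry.cross_link_acceptor}
    for p in mod.cv_params:
        if isinstance(p, m.CvParam) and p.accession not in skip:
            return p.accession
    return f"{mod.monoisotopic_mass_delta:.4f}"


# ---------------------------------------------------------------------------
# cross-linking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossLinkPair:
    """A resolved cross-linked identification: donor chain, acceptor chain(s)
    and the tied-rank PSM couple that reported them."""

    link_value: str
    donor_peptide_ref: str
    acceptor_peptide_refs: tuple[str, ...]
    sii_ids: tuple[str, ...]
    shared_rank: int
    shared_scores: tuple[tuple[str, str], ...]  # (accession, value)


def resolve_crosslink_pairs(result: m.SpectrumIdentificationResult,
                            doc: m.Document,
                            cv: CvGraph | None = None,
                            registry: TermRegistry = DEFAULT_REGISTRY,
                            ) -> list[CrossLinkPair]:
    """Group a spectrum's PSMs into cross-link pairs via the pairing term.

    Raises :class:`CrossLinkError` for unpaired values, mixed ranks or a
    donor count other than one among the linked peptides.
    """
    cv = cv or _default_cv()
    index = doc.index()
    groups: dict[str, list[m.SpectrumIdentificationItem]] = {}
    for item in result.items:
        p = item.param(registry.cross_link_sii)
        if p is not None and p.value is not None:
            groups.setdefault(p.value, []).append(item)

    pairs: list[CrossLinkPair] = []
    for value in sorted(groups):
        members = groups[value]
        if len(members) < 2:
            raise CrossLinkError(
                f"pairing value {value!r} in result {result.id} is unpaired"
            )
        ranks = {it.rank for it in members}
        if len(ranks) != 1:
            raise CrossLinkError(
                f"pairing value {value!r} spans ranks {sorted(ranks)}; "
                "paired items must share the rank"
            )
        donors: list[tuple[str, str]] = []   # (link value, peptide id)
        acceptors: list[str] = []
        for it in members:
            pep = index.get(it.peptide_ref)
            if not isinstance(pep, m.Peptide):
                continue
            for mod in pep.modifications:
                d = mod.param(registry.cross_link_donor)
                if d is not None:
                    donors.append((d.value or "", pep.id))
                a = mod.param(registry.cross_link_acceptor)
                if a is not None:
                    acceptors.append(pep.id)
        if len(donors) != 1:
            raise CrossLinkError(
                f"pairing value {value!r}: expected exactly one cross-link donor "
                f"among the linked peptides, found {len(donors)}"
            )
        link_value, donor_pep = donors[0]
        score_branch = cv.descendants(registry.psm_score_root)
        shared: set[tuple[str, str]] | None = None
        for it in members:
            mine = {(p.accession, p.value or "") for p in it.cv_params
                    if isinstance(p, m.CvParam)
                    and p.accession != registry.cross_link_sii
                    and p.accession in score_branch}
            shared = mine if shared is None else shared & mine
        pairs.append(CrossLinkPair(
            link_value=link_value,
            donor_peptide_ref=donor_pep,
            acceptor_peptide_refs=tuple(sorted(set(acceptors))),
            sii_ids=tuple(sorted(it.id for it in members)),
            shared_rank=next(iter(ranks)),
            shared_scores=tuple(sorted(shared or set())),
        ))
    return pairs


def all_crosslink_pairs(doc: m.Document, cv: CvGraph | None = None,
                        registry: TermRegistry = DEFAULT_REGISTRY) -> list[CrossLinkPair]:
    out: list[CrossLinkPair] = []
    for sil in doc.spectrum_identification_lists:
        for result in sil.results:
            out.extend(resolve_crosslink_pairs(result, doc, cv, registry))
    return out


# ---------------------------------------------------------------------------
# peptide-level grouping and target-decoy FDR
# ---------------------------------------------------------------------------

class GroupingMode(enum.Enum):
    SEQUENCE = GROUP_BY_SEQUENCE
    SEQUENCE_MODS = GROUP_BY_SEQUENCE_MODS
    SEQUENCE_MODS_CHARGE = GROUP_BY_SEQUENCE_MODS_CHARGE

    @classmethod
    def from_accession(cls, accession: str) -> "GroupingMode":
        for mode in cls:
            if mode.value == accession:
                return mode
        raise KeyError(accession)


@dataclass
class PeptideGroup:
    """A non-redundant peptide unit: the PSMs collapsed under one grouping key."""

    group_id: str
    mode: GroupingMode
    member_sii_ids: list[str]
    is_decoy: bool
    best_psm_score: float
    peptide_level_score: Optional[float] = None
    q_value: Optional[float] = None


def grouping_key(peptide: m.Peptide, charge: int, mode: GroupingMode,
                 registry: TermRegistry = DEFAULT_REGISTRY) -> str:
    """The deterministic key a PSM maps to under *mode* (also the group id)."""
    key = peptide.sequence.upper()
    if mode is GroupingMode.SEQUENCE:
        return key
    mods = sorted(
        (mod.location, _modification_identity(mod, registry))
        for mod in peptide.modifications
    )
    key += "|" + ";".join(f"{loc}:{ident}" for loc, ident in mods)
    if mode is GroupingMode.SEQUENCE_MODS:
        return key
    return key + f"|z={charge}"


def group_psms(sil: m.SpectrumIdentificationList, doc: m.Document,
               mode: GroupingMode,
               score_accession: str = MSGF_RAW_SCORE,
               higher_is_better: bool = True,
               registry: TermRegistry = DEFAULT_REGISTRY) -> list[PeptideGroup]:
    """Partition a result list's PSMs into peptide groups under *mode*.

    A group is flagged decoy only when every member PSM maps exclusively to
    decoy evidence (the conservative convention: mixed groups count as
    target).  The best PSM score per group follows *higher_is_better*.
    """
    index = doc.index()
    buckets: dict[str, list[m.SpectrumIdentificationItem]] = {}
    for result in sil.results:
        for item in result.items:
            pep = index.get(item.peptide_ref)
            if not isinstance(pep, m.Peptide):
                continue
            buckets.setdefault(
                grouping_key(pep, item.charge_state, mode, registry), []
            ).append(item)

    groups: list[PeptideGroup] = []
    for key in sorted(buckets):
        members = buckets[key]
        decoy_states: list[bool] = []
        scores: list[float] = []
        for item in members:
            evid = [index[r] for r in item.peptide_evidence_refs if r in index]
            decoy_states.append(bool(evid) and all(pe.is_decoy for pe in evid))
            p = item.param(score_accession)
            if p is not None and p.value is not None:
                scores.append(float(p.value))
        if not scores:
            scores = [float("-inf") if higher_is_better else float("inf")]
        groups.append(PeptideGroup(
            group_id=key,
            mode=mode,
            member_sii_ids=sorted(item.id for item in members),
            is_decoy=bool(decoy_states) and all(decoy_states),
            best_psm_score=max(scores) if higher_is_better else min(scores),
        ))
    return groups


def peptide_fdr(groups: Sequence[PeptideGroup],
                higher_is_better: bool = True) -> list[PeptideGroup]:
    """Annotate groups with target-decoy q-values.

    Groups are sorted best score first; at each depth k the FDR estimate is
    ``decoys(k) / max(1, targets(k))`` and the q-value is the running
    minimum of that ratio taken from the worst cut upward, so q-values are
    monotone non-increasing toward better scores.  With no decoys every
    q-value is 0.
    """
    ordered = sorted(
        groups,
        key=lambda g: ((-g.best_psm_score if higher_is_better else g.best_psm_score),
                       g.group_id),
    )
    if ordered and all(g.is_decoy for g in ordered):
        warnings.warn("all groups are decoy; q-values are uninformative", stacklevel=2)
    fdrs: list[float] = []
    n_decoy = n_target = 0
    for g in ordered:
        if g.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(1, n_target))
    out: list[PeptideGroup] = [replace(g) for g in ordered]
    running = float("inf")
    for i in range(len(out) - 1, -1, -1):
        running = min(running, fdrs[i])
        out[i].q_value = running
    return out


def apply_peptide_annotations(doc: m.Document, groups: Sequence[PeptideGroup],
                              threshold: float,
                              cv: CvGraph | None = None,
                              registry: TermRegistry = DEFAULT_REGISTRY) -> m.Document:
    """Write peptide-group ids and shared q-values back onto every member PSM.

    The protocol gains the peptide-level flag, the grouping-mode term and a
    q-value threshold declaration; member PSMs get ``pass_threshold``
    according to their group q-value.  Refuses to overwrite a document that
    already carries a different grouping (no silent re-annotation).
    """
    cv = cv or _default_cv()
    if not groups:
        return doc
    mode = groups[0].mode
    assignment: dict[str, PeptideGroup] = {}
    for g in groups:
        for sii_id in g.member_sii_ids:
            assignment[sii_id] = g

    index = doc.index()
    for sii_id in assignment:
        item = index.get(sii_id)
        if isinstance(item, m.SpectrumIdentificationItem):
            existing = item.param(registry.peptide_group_id)
            if existing is not None and existing.value != assignment[sii_id].group_id:
                raise AnnotationError(
                    f"PSM {sii_id} already belongs to group {existing.value!r}"
                )
    for prot in doc.protocols:
        for p in prot.additional_search_params:
            if (isinstance(p, m.CvParam) and p.accession in registry.grouping_modes
                    and p.accession != mode.value):
                raise AnnotationError(
                    f"document already declares grouping mode {p.accession}"
                )

    def q_string(g: PeptideGroup) -> str:
        return f"{g.q_value:.6g}" if g.q_value is not None else "1"

    for sii_id, g in assignment.items():
        item = index[sii_id]
        if item.param(registry.peptide_group_id) is None:
            item.cv_params.append(m.CvParam(
                registry.peptide_group_id, cv.name_of(registry.peptide_group_id),
                value=g.group_id,
            ))
        if item.param(registry.peptide_qvalue) is None:
            item.cv_params.append(m.CvParam(
                registry.peptide_qvalue, cv.name_of(registry.peptide_qvalue),
                value=q_string(g),
            ))
        if g.q_value is not None:
            item.pass_threshold = g.q_value <= threshold

    for prot in doc.protocols:
        present = {p.accession for p in prot.additional_search_params
                   if isinstance(p, m.CvParam)}
        if PEPTIDE_LEVEL_SCORING not in present:
            prot.additional_search_params.append(m.CvParam(
                PEPTIDE_LEVEL_SCORING, cv.name_of(PEPTIDE_LEVEL_SCORING)))
        if mode.value not in present:
            prot.additional_search_params.append(m.CvParam(
                mode.value, cv.name_of(mode.value)))
        if registry.peptide_qvalue not in {
            p.accession for p in prot.threshold if isinstance(p, m.CvParam)
        }:
            prot.threshold = [p for p in prot.threshold
                              if not (isinstance(p, m.CvParam)
                                      and p.accession == "MS:1001494")]
            prot.threshold.append(m.CvParam(
                registry.peptide_qvalue, cv.name_of(registry.peptide_qvalue),
                value=repr(float(threshold)),
            ))
    return doc


# ---------------------------------------------------------------------------
# proteogenomics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicMapping:
    """A peptide's footprint on the genome as 1-based inclusive exon blocks."""

    chromosome: str
    strand: str
    genome_build: str
    blocks: tuple[tuple[int, int], ...]
    exon_count: int

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


def genomic_mapping(pe: m.PeptideEvidence, dbs: m.DBSequence, peptide: m.Peptide,
                    registry: TermRegistry = DEFAULT_REGISTRY) -> GenomicMapping:
    """Decode the coordinate params into a checked :class:`GenomicMapping`.

    Enforces the coding-region arithmetic: blocks are sorted and disjoint,
    the declared exon count equals the block count, and the block lengths
    sum to three nucleotides per residue.
    """
    def need(holder, acc: str, what: str) -> str:
        p = holder.param(acc)
        if p is None or p.value is None:
            raise MappingError(f"{what} missing param {acc} on {holder.id}")
        return p.value

    starts_raw = need(pe, registry.pg_start_positions, "PeptideEvidence")
    ends_raw = need(pe, registry.pg_end_positions, "PeptideEvidence")
    exon_raw = need(pe, registry.pg_exon_count, "PeptideEvidence")
    build = need(dbs, registry.pg_genome_build, "DBSequence")
    chrom = need(dbs, registry.pg_chromosome, "DBSequence")
    strand = need(dbs, registry.pg_strand, "DBSequence")

    try:
        starts = [int(x) for x in starts_raw.split(",")]
        ends = [int(x) for x in ends_raw.split(",")]
        exon_count = int(exon_raw)
    except ValueError as exc:
        raise MappingError(f"non-integer coordinate on {pe.id}: {exc}") from None
    if len(starts) != len(ends):
        raise MappingError(
            f"{pe.id}: {len(starts)} block starts vs {len(ends)} block ends"
        )
    blocks = sorted(zip(starts, ends))
    for (s, e) in blocks:
        if e < s:
            raise MappingError(f"{pe.id}: block end {e} before start {s}")
    for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
        if s2 <= e1:
            raise MappingError(f"{pe.id}: overlapping blocks at {s2}")
    if exon_count != len(blocks):
        raise MappingError(
            f"{pe.id}: exon count {exon_count} != {len(blocks)} blocks"
        )
    if strand not in ("+", "-"):
        raise MappingError(f"{dbs.id}: strand must be '+' or '-', got {strand!r}")
    total = sum(e - s + 1 for s, e in blocks)
    if total != 3 * len(peptide.sequence):
        raise MappingError(
            f"{pe.id}: blocks cover {total} nt but peptide "
            f"{peptide.id} needs {3 * len(peptide.sequence)}"
        )
    return GenomicMapping(
        chromosome=chrom, strand=strand, genome_build=build,
        blocks=tuple(blocks), exon_count=exon_count,
    )


def all_genomic_mappings(doc: m.Document,
                         registry: TermRegistry = DEFAULT_REGISTRY,
                         ) -> list[tuple[str, GenomicMapping]]:
    """(peptide label, mapping) for every evidence carrying coordinates."""
    index = doc.index()
    out: list[tuple[str, GenomicMapping]] = []
    for pe in doc.peptide_evidences:
        if pe.param(registry.pg_start_positions) is None:
            continue
        dbs = index[pe.db_sequence_ref]
        pep = index[pe.peptide_ref]
        out.append((f"{pep.sequence}_{pe.id}", genomic_mapping(pe, dbs, pep, registry)))
    return out


def export_bed(mappings: Iterable[tuple[str, GenomicMapping]]) -> str:
    """Serialize mappings as BED12 (0-based half-open, ascending blocks)."""
    lines = []
    for name, gm in mappings:
        chrom_start = gm.blocks[0][0] - 1
        chrom_end = gm.blocks[-1][1]
        sizes = [e - s + 1 for s, e in gm.blocks]
        starts = [s - 1 - chrom_start for s, _ in gm.blocks]
        lines.append("\t".join(str(x) for x in (
            gm.chromosome, chrom_start, chrom_end, name, 0, gm.strand,
            chrom_start, chrom_end, "0", len(gm.blocks),
            ",".join(map(str, sizes)), ",".join(map(str, starts)),
        )))
    return "\n".join(lines) + ("\n" if lines else "")


def read_bed(text: str) -> list[tuple[str, GenomicMapping]]:
    """Parse BED12 back into 1-based inclusive mappings (build unknown)."""
    out: list[tuple[str, GenomicMapping]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = tuple(
            (chrom_start + st + 1, chrom_start + st + sz)
            for st, sz in zip(starts, sizes)
        )
        out.append((name, GenomicMapping(
            chromosome=chrom, strand=strand, genome_build="",
            blocks=blocks, exon_count=len(blocks),
        )))
    return out


# ---------------------------------------------------------------------------
# tabular exports
# ---------------------------------------------------------------------------

def sites_table(doc: m.Document, cv: CvGraph | None = None,
                registry: TermRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
    rows = confident_sites(doc, cv, registry)
    return pd.DataFrame(rows, columns=["accession", "position", "modification", "score"])


def crosslink_table(doc: m.Document, cv: CvGraph | None = None,
                    registry: TermRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
    rows = []
    for pair in all_crosslink_pairs(doc, cv, registry):
        score = pair.shared_scores[0][1] if pair.shared_scores else ""
        rows.append((pair.link_value, pair.donor_peptide_ref,
                     ";".join(pair.acceptor_peptide_refs),
                     ";".join(pair.sii_ids), pair.shared_rank, score))
    return pd.DataFrame(rows, columns=[
        "link_value", "donor_peptide", "acceptor_peptides", "psm_ids",
        "rank", "shared_score"])


def peptide_table(doc: m.Document, mode: GroupingMode,
                  higher_is_better: bool = True,
                  registry: TermRegistry = DEFAULT_REGISTRY) -> pd.DataFrame:
    rows = []
    for sil in doc.spectrum_identification_lists:
        groups = peptide_fdr(
            group_psms(sil, doc, mode, registry=registry,
                       higher_is_better=higher_is_better),
            higher_is_better,
        )
        for g in groups:
            rows.append((sil.id, g.group_id, g.is_decoy, len(g.member_sii_ids),
                         g.best_psm_score, g.q_value))
    return pd.DataFrame(rows, columns=[
        "sil_id", "group_id", "is_decoy", "n_psms", "best_psm_score", "q_value"])
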
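"""Semantic validation of mzIdentML documents.

Two layers of rules run over a parsed :class:`~mzidkit.model.Document`:

* **generic CV mapping rules** — data-driven ``(scope, level, branch
  roots, cardinality)`` entries in the style of the PSI CV mapping file,
  loadable from JSON so deployments can edit them without code changes;
* **built-in conditional rules** — cross-element checks activated by the
  workflow flag(s) a 1.2 protocol declares (modification localization,
  cross-linking, peptide-level statistics, proteogenomics, the relaxed
  evidence cardinality for de novo / spectral library results, and the
  one-result-per-spectrum constraint).

Requirement levels map MAY→info, SHOULD→warning, MUST→error; a document
is valid iff validation yields zero error-level messages.  Problems are
messages, never exceptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Optional, Sequence

from . import model as m
from . import terms as t
from .cv import CvGraph, load_default_cv
from .terms import DEFAULT_REGISTRY, TermRegistry
from .workflows import GroupingMode, grouping_key

_LEVEL_FOR = {"MAY": "info", "SHOULD": "warning", "MUST": "error"}


@dataclass(frozen=True)
class ValidationMessage:
    rule_id: str
    level: str  # info | warning | error
    locus: str
    text: str


@dataclass(frozen=True)
class CvRule:
    """One generic mapping rule: which branch terms may/should/must appear
    where, and how many times."""

    rule_id: str
    scope: str
    level: str  # MAY | SHOULD | MUST
    branch_roots: tuple[str, ...]
    min: int = 0
    max: Optional[int] = None

    def __post_init__(self):
        if self.level not in _LEVEL_FOR:
            raise ValueError(f"level must be MAY/SHOULD/MUST, got {self.level!r}")
        if self.max is not None and self.min > self.max:
            raise ValueError("rule cardinality min > max")


@dataclass
class ValidatorConfig:
    """Switches for the points the format guidance leaves open."""

    #: enforce file-wide spectrum-identifier uniqueness on every 1.2 document
    #: (not only consensus-flagged ones)
    unique_spectrum_ids: bool = True
    #: when set, "identical score" comparisons accept this relative numeric
    #: tolerance instead of exact string equality
    score_tolerance: Optional[float] = None


def load_ruleset(path: str | None = None) -> list[CvRule]:
    """Load generic rules from JSON (default: the vendored ruleset)."""
    if path is None:
        text = (files("mzidkit") / "data" / "default-rules.json").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = json.loads(text)
    return [
        CvRule(
            rule_id=r["rule_id"], scope=r["scope"], level=r["level"],
            branch_roots=tuple(r["branch_roots"]),
            min=r.get("min", 0), max=r.get("max"),
        )
        for r in raw["rules"]
    ]


def is_valid(messages: Sequence[ValidationMessage]) -> bool:
    return not any(msg.level == "error" for msg in messages)


# ---------------------------------------------------------------------------

class _Collector:
    """Accumulates messages tagged with a document-order position."""

    def __init__(self, doc: m.Document):
        self.messages: list[tuple[int, ValidationMessage]] = []
        self.position: dict[str, int] = {}
        pos = 0
        for coll in (doc.db_sequences, doc.peptides, doc.peptide_evidences,
                     doc.protocols):
            for el in coll:
                self.position[el.id] = pos
                pos += 1
        for sil in doc.spectrum_identification_lists:
            self.position[sil.id] = pos
            pos += 1
            for result in sil.results:
                self.position[result.id] = pos
                pos += 1
                for item in result.items:
                    self.position[item.id] = pos
                    pos += 1
        for pdl in doc.protein_detection_lists:
            self.position[pdl.id] = pos
            pos += 1

    def add(self, rule_id: str, level: str, locus_kind: str,
            el_id: str | None, text: str) -> None:
        locus = f"{locus_kind}[{el_id}]" if el_id else locus_kind
        pos = self.position.get(el_id, -1) if el_id else -1
        self.messages.append(
            (pos, ValidationMessage(rule_id, level, locus, text))
        )

    def sorted(self) -> list[ValidationMessage]:
        return [msg for _pos, msg in
                sorted(self.messages, key=lambda pm: (pm[0], pm[1].rule_id))]


def validate(doc: m.Document,
             ruleset: Sequence[CvRule] | None = None,
             cv: CvGraph | None = None,
             registry: TermRegistry = DEFAULT_REGISTRY,
             config: ValidatorConfig | None = None) -> list[ValidationMessage]:
    """Run every applicable rule and return the ordered message list."""
    cv = cv or load_default_cv()
    config = config or ValidatorConfig()
    if ruleset is None:
        ruleset = load_ruleset()
    out = _Collector(doc)
    flags = doc.workflow_flags() if doc.is_v12() else set()

    _rule_flag1(doc, out)
    for rule in ruleset:
        _apply_generic(doc, rule, cv, out)
    if t.MODIFICATION_LOCALIZATION_SCORING in flags:
        _rules_loc(doc, cv, registry, out)
    if t.CROSS_LINKING_SEARCH in flags:
        _rules_xl(doc, cv, registry, config, out)
    if t.PEPTIDE_LEVEL_SCORING in flags:
        _rules_pep(doc, cv, registry, config, out)
    _rule_card1(doc, flags, out)
    if doc.is_v12() and config.unique_spectrum_ids:
        _rule_uniq1(doc, out)
    if t.PROTEOGENOMICS_SEARCH in flags:
        _rules_pg(doc, registry, out)
    _rule_spec1(doc, flags, out)
    return out.sorted()


# -- file-level ------------------------------------------------------------

def _rule_flag1(doc: m.Document, out: _Collector) -> None:
    if doc.is_v12() and not doc.workflow_flags():
        out.add("FLAG-1", "error", "SpectrumIdentificationProtocol", None,
                "a 1.2 document must declare at least one workflow flag "
                "in AdditionalSearchParams")


def _rule_uniq1(doc: m.Document, out: _Collector) -> None:
    seen: dict[tuple[str, str], str] = {}
    for sil in doc.spectrum_identification_lists:
        for result in sil.results:
            key = (result.spectra_data_ref, result.spectrum_id)
            if key in seen:
                out.add("UNIQ-1", "error", "SpectrumIdentificationResult",
                        result.id,
                        f"spectrum {result.spectrum_id!r} already reported "
                        f"by result {seen[key]}; one result per spectrum")
            else:
                seen[key] = result.id


def _rule_card1(doc: m.Document, flags: set[str], out: _Collector) -> None:
    relaxed = bool(flags & {t.DE_NOVO_SEARCH, t.SPECTRAL_LIBRARY_SEARCH})
    if relaxed:
        return
    for _sil, _res, item in doc.iter_items():
        if not item.peptide_evidence_refs:
            out.add("CARD-1", "error", "SpectrumIdentificationItem", item.id,
                    "PSM records no peptide-to-protein relationship and no "
                    "de novo / spectral library flag is declared")


def _rule_spec1(doc: m.Document, flags: set[str], out: _Collector) -> None:
    if t.SPECTRAL_LIBRARY_SEARCH in flags:
        return
    for pep in doc.peptides:
        if not pep.sequence:
            out.add("SPEC-1", "error", "Peptide", pep.id,
                    "empty peptide sequence is only allowed under the "
                    "spectral library search flag")


# -- generic mapping rules -------------------------------------------------

def _scope_instances(doc: m.Document, scope: str):
    if scope == "SpectrumIdentificationProtocol/SearchType":
        for prot in doc.protocols:
            yield prot.id, [prot.search_type]
    elif scope == "SpectrumIdentificationProtocol/AdditionalSearchParams":
        for prot in doc.protocols:
            yield prot.id, prot.additional_search_params
    elif scope == "SpectrumIdentificationProtocol/Threshold":
        for prot in doc.protocols:
            yield prot.id, prot.threshold
    elif scope == "SpectrumIdentificationItem":
        for _sil, _res, item in doc.iter_items():
            yield item.id, item.cv_params
    elif scope == "SpectrumIdentificationResult":
        for sil in doc.spectrum_identification_lists:
            for result in sil.results:
                yield result.id, result.cv_params
    elif scope == "Peptide":
        for pep in doc.peptides:
            yield pep.id, pep.cv_params
    elif scope == "Modification":
        for pep in doc.peptides:
            for i, mod in enumerate(pep.modifications):
                yield f"{pep.id}/mod{i}", mod.cv_params
    elif scope == "PeptideEvidence":
        for pe in doc.peptide_evidences:
            yield pe.id, pe.cv_params
    elif scope == "DBSequence":
        for dbs in doc.db_sequences:
            yield dbs.id, dbs.cv_params
    elif scope == "ProteinDetectionHypothesis":
        for pdl in doc.protein_detection_lists:
            for group in pdl.groups:
                for pdh in group.hypotheses:
                    yield pdh.id, pdh.cv_params
    else:
        raise ValueError(f"unsupported rule scope {scope!r}")


def _apply_generic(doc: m.Document, rule: CvRule, cv: CvGraph,
                   out: _Collector) -> None:
    level = _LEVEL_FOR[rule.level]
    for el_id, params in _scope_instances(doc, rule.scope):
        n = sum(
            1 for p in params
            if isinstance(p, m.CvParam) and p.accession in cv
            and any(cv.in_branch(p.accession, root) for root in rule.branch_roots)
        )
        if n < rule.min:
            out.add(rule.rule_id, level, rule.scope, el_id,
                    f"expected at least {rule.min} term(s) from "
                    f"{'/'.join(rule.branch_roots)}, found {n}")
        elif rule.max is not None and n > rule.max:
            out.add(rule.rule_id, level, rule.scope, el_id,
                    f"expected at most {rule.max} term(s) from "
                    f"{'/'.join(rule.branch_roots)}, found {n}")


# -- modification localization ---------------------------------------------

def _rules_loc(doc: m.Document, cv: CvGraph, registry: TermRegistry,
               out: _Collector) -> None:
    loc_terms = cv.descendants(registry.localization_score_root)
    index = doc.index()

    for pep in doc.peptides:
        seen: set[int] = set()
        for i, mod in enumerate(pep.modifications):
            idx_params = [p for p in mod.cv_params
                          if isinstance(p, m.CvParam)
                          and p.accession == registry.modification_index]
            if len(idx_params) != 1:
                out.add("LOC-1", "error", "Peptide", pep.id,
                        f"modification {i} carries {len(idx_params)} "
                        "modification-index terms (exactly one required)")
                continue
            try:
                value = int(idx_params[0].value or "")
            except ValueError:
                out.add("LOC-1", "error", "Peptide", pep.id,
                        f"modification {i} index {idx_params[0].value!r} "
                        "is not an integer")
                continue
            if value in seen:
                out.add("LOC-1", "error", "Peptide", pep.id,
                        f"modification index {value} reused within the peptide")
            seen.add(value)

    for _sil, _res, item in doc.iter_items():
        pep = index.get(item.peptide_ref)
        if not isinstance(pep, m.Peptide):
            continue
        declared = pep.modification_indices(registry.modification_index)
        upper = len(pep.sequence) + 1
        for param in item.cv_params:
            if not isinstance(param, m.CvParam) or param.accession not in loc_terms:
                continue
            value = param.value or ""
            fields = value.split(":")
            if len(fields) != 4:
                out.add("LOC-2", "error", "SpectrumIdentificationItem", item.id,
                        f"localization score {value!r} has {len(fields)} "
                        "fields; the grammar requires "
                        "MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD")
                continue
            raw_index, raw_score, raw_pos, raw_pass = fields
            try:
                mod_index = int(raw_index)
                float(raw_score)
                positions = [int(p) for p in raw_pos.split("|")]
            except ValueError:
                out.add("LOC-2", "error", "SpectrumIdentificationItem", item.id,
                        f"localization score {value!r} has a non-numeric field")
                continue
            if raw_pass.lower() not in ("true", "false"):
                out.add("LOC-2", "error", "SpectrumIdentificationItem", item.id,
                        f"PASS_THRESHOLD must be true/false in {value!r}")
                continue
            if mod_index not in declared:
                out.add("LOC-3", "error", "SpectrumIdentificationItem", item.id,
                        f"score references modification index {mod_index}, "
                        f"peptide {pep.id} declares {sorted(declared)}")
                continue
            for p in positions:
                if not 0 <= p <= upper:
                    out.add("LOC-4", "error", "SpectrumIdentificationItem",
                            item.id,
                            f"position {p} outside [0, {upper}] for peptide "
                            f"{pep.id}")


# -- cross-linking ----------------------------------------------------------

def _scores_equal(a: str, b: str, tolerance: Optional[float]) -> bool:
    if a == b:
        return True
    if tolerance is None:
        return False
    try:
        fa, fb = float(a), float(b)
    except ValueError:
        return False
    return abs(fa - fb) <= tolerance * max(1.0, abs(fa), abs(fb))


def _rules_xl(doc: m.Document, cv: CvGraph, registry: TermRegistry,
              config: ValidatorConfig, out: _Collector) -> None:
    donors: dict[str, int] = {}
    acceptors: dict[str, int] = {}
    for pep in doc.peptides:
        for mod in pep.modifications:
            d = mod.param(registry.cross_link_donor)
            if d is not None:
                donors[d.value or ""] = donors.get(d.value or "", 0) + 1
            a = mod.param(registry.cross_link_acceptor)
            if a is not None:
                acceptors[a.value or ""] = acceptors.get(a.value or "", 0) + 1
                if mod.monoisotopic_mass_delta != 0:
                    out.add("XL-2", "error", "Peptide", pep.id,
                            "cross-link acceptor must report a zero mass "
                            f"delta, found {mod.monoisotopic_mass_delta}")
    for value in sorted(donors.keys() | acceptors.keys()):
        nd, na = donors.get(value, 0), acceptors.get(value, 0)
        if nd != 1 or na < 1:
            out.add("XL-1", "error", "Peptide", None,
                    f"link value {value!r} has {nd} donor and {na} acceptor "
                    "modifications (need exactly one donor, at least one "
                    "acceptor)")

    score_branch = cv.descendants(registry.psm_score_root)
    for sil in doc.spectrum_identification_lists:
        for result in sil.results:
            groups: dict[str, list[m.SpectrumIdentificationItem]] = {}
            for item in result.items:
                p = item.param(registry.cross_link_sii)
                if p is not None and p.value is not None:
                    groups.setdefault(p.value, []).append(item)
            for value in sorted(groups):
                members = groups[value]
                if len(members) < 2:
                    out.add("XL-5", "error", "SpectrumIdentificationResult",
                            result.id,
                            f"pairing value {value!r} is carried by a single "
                            "PSM; cross-linked chains come in pairs")
                    continue
                if len({it.rank for it in members}) != 1:
                    out.add("XL-3", "error", "SpectrumIdentificationResult",
                            result.id,
                            f"PSMs sharing pairing value {value!r} do not "
                            "share the rank attribute")
                member_scores = [
                    [(p.accession, p.value or "") for p in it.cv_params
                     if isinstance(p, m.CvParam) and p.accession in score_branch]
                    for it in members
                ]
                first = member_scores[0]
                shared = [
                    (acc, val) for acc, val in first
                    if all(any(acc == a2 and _scores_equal(val, v2, config.score_tolerance)
                               for a2, v2 in other)
                           for other in member_scores[1:])
                ]
                if not shared:
                    out.add("XL-4", "error", "SpectrumIdentificationResult",
                            result.id,
                            f"PSMs sharing pairing value {value!r} carry no "
                            "identical score term")


# -- peptide-level statistics -----------------------------------------------

def _rules_pep(doc: m.Document, cv: CvGraph, registry: TermRegistry,
               config: ValidatorConfig, out: _Collector) -> None:
    mode_terms = []
    for prot in doc.protocols:
        for p in prot.additional_search_params:
            if isinstance(p, m.CvParam) and p.accession in registry.grouping_modes:
                mode_terms.append(p.accession)
    if len(mode_terms) != 1:
        out.add("PEP-2", "error", "SpectrumIdentificationProtocol", None,
                f"found {len(mode_terms)} PSM-grouping mode terms; exactly "
                "one of the three grouping modes must be declared")

    pep_branch = cv.descendants(registry.peptide_score_root)
    by_group: dict[str, list[m.SpectrumIdentificationItem]] = {}
    for _sil, _res, item in doc.iter_items():
        group_params = [p for p in item.cv_params
                        if isinstance(p, m.CvParam)
                        and p.accession == registry.peptide_group_id]
        if len(group_params) != 1:
            out.add("PEP-1", "error", "SpectrumIdentificationItem", item.id,
                    f"PSM carries {len(group_params)} peptide-group-ID terms "
                    "(exactly one required)")
            continue
        by_group.setdefault(group_params[0].value or "", []).append(item)

    for group_id in sorted(by_group):
        members = by_group[group_id]
        reference = {(p.accession, p.value or "") for p in members[0].cv_params
                     if isinstance(p, m.CvParam) and p.accession in pep_branch}
        for item in members[1:]:
            mine = {(p.accession, p.value or "") for p in item.cv_params
                    if isinstance(p, m.CvParam) and p.accession in pep_branch}
            same = mine == reference or (
                config.score_tolerance is not None
                and {a for a, _ in mine} == {a for a, _ in reference}
                and all(any(a1 == a2 and _scores_equal(v1, v2, config.score_tolerance)
                            for a2, v2 in reference) for a1, v1 in mine)
            )
            if not same:
                out.add("PEP-3", "error", "SpectrumIdentificationItem", item.id,
                        f"peptide-level score differs within group {group_id!r}")

    if len(mode_terms) == 1:
        try:
            mode = GroupingMode.from_accession(mode_terms[0])
        except KeyError:
            return
        index = doc.index()
        group_to_keys: dict[str, set[str]] = {}
        key_to_groups: dict[str, set[str]] = {}
        for group_id, members in by_group.items():
            for item in members:
                pep = index.get(item.peptide_ref)
                if not isinstance(pep, m.Peptide):
                    continue
                key = grouping_key(pep, item.charge_state, mode, registry)
                group_to_keys.setdefault(group_id, set()).add(key)
                key_to_groups.setdefault(key, set()).add(group_id)
        for group_id in sorted(group_to_keys):
            if len(group_to_keys[group_id]) > 1:
                out.add("PEP-4", "warning", "SpectrumIdentificationItem", None,
                        f"group {group_id!r} mixes {len(group_to_keys[group_id])} "
                        f"distinct {mode.name} keys")
        for key in sorted(key_to_groups):
            if len(key_to_groups[key]) > 1:
                out.add("PEP-4", "warning", "SpectrumIdentificationItem", None,
                        f"{mode.name} key {key!r} is split across groups "
                        f"{sorted(key_to_groups[key])}")


# -- proteogenomics ----------------------------------------------------------

def _rules_pg(doc: m.Document, registry: TermRegistry, out: _Collector) -> None:
    index = doc.index()
    for pe in doc.peptide_evidences:
        missing = [acc for acc in registry.pg_evidence_params
                   if pe.param(acc) is None]
        if missing:
            out.add("PG-1", "error", "PeptideEvidence", pe.id,
                    f"missing peptide-coordinate param(s) {missing}")
            continue
        dbs = index.get(pe.db_sequence_ref)
        if isinstance(dbs, m.DBSequence):
            missing_db = [acc for acc in registry.pg_dbsequence_params
                          if dbs.param(acc) is None]
            if missing_db:
                out.add("PG-2", "error", "DBSequence", dbs.id,
                        f"missing gene-model param(s) {missing_db}")
        starts_raw = pe.param(registry.pg_start_positions).value or ""
        exon_raw = pe.param(registry.pg_exon_count).value or ""
        try:
            n_blocks = len(starts_raw.split(","))
            exon_count = int(exon_raw)
        except ValueError:
            out.add("PG-3", "error", "PeptideEvidence", pe.id,
                    f"non-integer exon count {exon_raw!r}")
            continue
        if exon_count != n_blocks:
            out.add("PG-3", "error", "PeptideEvidence", pe.id,
                    f"declared exon count {exon_count} but {n_blocks} "
                    "coordinate blocks")


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def report_tsv(messages: Sequence[ValidationMessage]) -> str:
    lines = ["rule_id\tlevel\tlocus\ttext"]
    for msg in messages:
        lines.append(f"{msg.rule_id}\t{msg.level}\t{msg.locus}\t{msg.text}")
    return "\n".join(lines) + "\n"


def report_json(messages: Sequence[ValidationMessage]) -> str:
    return json.dumps(
        [{"rule_id": msg.rule_id, "level": msg.level,
          "locus": msg.locus, "text": msg.text} for msg in messages],
        indent=2,
    ) + "\n"
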
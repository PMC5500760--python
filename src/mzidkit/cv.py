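"""Controlled-vocabulary engine.

Loads OBO 1.2-style term stanzas into an in-memory graph and answers the
hierarchy queries (ancestor closure, branch membership) that semantic
validation rules are written against.  Only the stanza subset the PSI
formats rely on is interpreted: ``id``, ``name``, ``is_a`` and
``is_obsolete``.  A full PSI-MS OBO release loads through the same code
path as the vendored subset shipped under ``mzidkit/data``.
"""

from __future__ import annotations

import graphlib
import re
from dataclasses import dataclass, field
from importlib.resources import files
from typing import IO, Iterable

from .errors import CvLookupError, CvStructureError, OboParseError

_ACCESSION_RE = re.compile(r"^[A-Za-z]+:\d+$")


@dataclass(frozen=True)
class CvTerm:
    """One vocabulary term: accession, preferred name and its is_a parents."""

    accession: str
    name: str
    parents: frozenset[str] = frozenset()
    is_obsolete: bool = False
    source_cv: str = "MS"


@dataclass
class CvGraph:
    """Acyclic is_a graph over :class:`CvTerm` objects, keyed by accession."""

    terms: dict[str, CvTerm] = field(default_factory=dict)

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, accession: str) -> CvTerm:
        try:
            return self.terms[accession]
        except KeyError:
            raise CvLookupError(f"unknown CV accession {accession!r}") from None

    @property
    def roots(self) -> set[str]:
        """Terms with no in-graph parent (dangling parents count as external)."""
        return {
            a for a, t in self.terms.items()
            if not any(p in self.terms for p in t.parents)
        }

    def name_of(self, accession: str) -> str:
        return self[accession].name

    def closure(self, accession: str) -> set[str]:
        """The accession plus all its is_a ancestors (reflexive-transitive)."""
        out: set[str] = set()
        stack = [self[accession].accession]
        while stack:
            acc = stack.pop()
            if acc in out or acc not in self.terms:
                continue
            out.add(acc)
            stack.extend(self.terms[acc].parents)
        return out

    def in_branch(self, accession: str, branch_root: str) -> bool:
        """True iff *branch_root* is the term itself or one of its ancestors."""
        self[branch_root]  # raise for unknown root too
        return branch_root in self.closure(accession)

    def descendants(self, branch_root: str) -> set[str]:
        """All terms whose closure contains *branch_root* (root included)."""
        return {a for a in self.terms if branch_root in self.closure(a)}

    def merged_with(self, other: "CvGraph") -> "CvGraph":
        clash = self.terms.keys() & other.terms.keys()
        if clash:
            raise CvStructureError(f"accession clash on merge: {sorted(clash)[:3]}")
        return CvGraph({**self.terms, **other.terms})

    def _check_acyclic(self) -> None:
        ts = graphlib.TopologicalSorter(
            {a: [p for p in t.parents if p in self.terms] for a, t in self.terms.items()}
        )
        try:
            ts.prepare()
        except graphlib.CycleError as exc:
            raise CvStructureError(f"is_a cycle in CV: {exc.args[1]}") from None


def _iter_lines(source: str | IO[str] | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        import os
        if "\n" in source or "[Term]" in source or not os.path.exists(source):
            return source.splitlines()
        return open(source, encoding="utf-8")
    return source


def load_cv(source: str | IO[str] | Iterable[str], source_cv: str | None = None) -> CvGraph:
    """Parse OBO stanza text into a :class:`CvGraph`.

    *source* may be a path, OBO text, an open stream or an iterable of lines.
    Raises :class:`OboParseError` (with line number) for malformed stanzas
    and :class:`CvStructureError` for is_a cycles.
    """
    terms: dict[str, CvTerm] = {}
    stanza: dict | None = None
    stanza_line = 0
    in_term = False

    def flush() -> None:
        nonlocal stanza
        if stanza is None:
            return
        acc = stanza.get("id")
        if acc is None:
            raise OboParseError("[Term] stanza without an id", stanza_line)
        if "name" not in stanza:
            raise OboParseError(f"term {acc} has no name", stanza_line)
        if not _ACCESSION_RE.match(acc):
            raise OboParseError(f"malformed accession {acc!r}", stanza_line)
        if acc in terms:
            raise OboParseError(f"duplicate term {acc}", stanza_line)
        terms[acc] = CvTerm(
            accession=acc,
            name=stanza["name"],
            parents=frozenset(stanza.get("is_a", ())),
            is_obsolete=stanza.get("is_obsolete", False),
            source_cv=source_cv or acc.split(":", 1)[0],
        )
        stanza = None

    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                stanza = {}
                stanza_line = lineno
            continue
        if ":" not in line:
            raise OboParseError(f"malformed OBO line {line!r}", lineno)
        if not in_term or stanza is None:
            continue  # header / [Typedef] content
        key, _, value = line.partition(":")
        value = value.split(" ! ")[0].strip()
        key = key.strip()
        if key == "id":
            stanza["id"] = value
        elif key == "name":
            stanza["name"] = value
        elif key == "is_a":
            stanza.setdefault("is_a", []).append(value)
        elif key == "is_obsolete":
            stanza["is_obsolete"] = value.lower() == "true"
    flush()

    graph = CvGraph(terms)
    graph._check_acyclic()
    return graph


def write_obo(graph: CvGraph) -> str:
    """Serialize a graph back to OBO text (terms sorted by accession)."""
    out = ["format-version: 1.2", ""]
    for acc in sorted(graph.terms):
        t = graph.terms[acc]
        out.append("[Term]")
        out.append(f"id: {t.accession}")
        out.append(f"name: {t.name}")
        for p in sorted(t.parents):
            out.append(f"is_a: {p}")
        if t.is_obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out)


def _data_text(name: str) -> str:
    return (files("mzidkit") / "data" / name).read_text(encoding="utf-8")


def load_psi_ms_subset() -> CvGraph:
    """The vendored PSI-MS working subset shipped with mzidkit."""
    return load_cv(_data_text("psi-ms-subset.obo"), source_cv="MS")


def load_xlmod_stub() -> CvGraph:
    """The vendored three-term XLMOD cross-linker stub."""
    return load_cv(_data_text("xlmod-stub.obo"), source_cv="XLMOD")


def load_default_cv() -> CvGraph:
    """PSI-MS subset merged with the XLMOD stub; the validator default."""
    return load_psi_ms_subset().merged_with(load_xlmod_stub())
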
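"""Exception hierarchy shared across mzidkit."""


class MzidError(Exception):
    """Base class for every error raised by mzidkit."""


class OboParseError(MzidError):
    """Malformed OBO input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CvStructureError(MzidError):
    """Structural defect in a controlled vocabulary (e.g. an is_a cycle)."""


class CvLookupError(MzidError, KeyError):
    """Accession not present in the controlled-vocabulary graph."""


class DuplicateIdError(MzidError):
    """Two elements registered under the same file-wide identifier."""


class DanglingReferenceError(MzidError):
    """A *_ref attribute points at an identifier that does not exist."""


class NotMzIdentMLError(MzidError):
    """The XML root element is not in an mzIdentML namespace."""


class VersionError(MzidError):
    """Missing or unsupported mzIdentML version."""


class SerializationError(MzidError):
    """Document violates a structural invariant and cannot be written."""


class ScoreGrammarError(MzidError):
    """Localization-score value does not match MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD."""


class ScoreReferenceError(MzidError):
    """Localization score references a modification index absent from its peptide."""


class ScoreRangeError(MzidError):
    """Localization-score position outside [0, peptide length + 1]."""


class CrossLinkError(MzidError):
    """Cross-link pair cannot be resolved (unpaired value, rank mix, donor cardinality)."""


class AnnotationError(MzidError):
    """Document already carries a conflicting peptide-level annotation."""


class MappingError(MzidError):
    """Genomic mapping parameters missing or inconsistent."""


class ParameterError(MzidError):
    """Invalid argument to a generator or CLI operation."""
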
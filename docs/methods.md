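# Methods

This note documents the models, conventions and design choices behind
mzidkit: what each component computes, the defaults and why, what the
synthetic fixtures emulate, and the known limitations.

## Data model and serialization

The object model mirrors the element structure shared by the mzIdentML
1.1 and 1.2 schemas: PSMs (`SpectrumIdentificationItem`) nested in
per-spectrum results and result lists, re-usable `Peptide` objects,
`PeptideEvidence` links to database proteins, and an optional
protein-inference section (at most one `ProteinDetectionList` per file —
the merged-fractions convention).  Identifiers are opaque strings with
*file-wide* uniqueness, enforced when the id registry is built
(`Document.index()`), not per class, because that is how the format
defines them.  Protein ambiguity groups and detection hypotheses are
stored and round-tripped but protein inference itself is out of scope.

Version handling is purely declarative: the namespace and the root
`version` attribute decide how a file is treated.  The two schema series
are nearly identical, so structural sniffing would be unreliable by
construction.  The writer is deterministic — elements in schema order,
siblings sorted by id, PSMs by (rank, id), floats in shortest
round-trippable form, UTF-8 output — so two writes of one document are
byte-identical and outputs diff cleanly.  Unknown root-level children are
preserved verbatim and re-emitted in place; unknown children nested
inside known elements are not preserved (a known limitation).
`passThreshold` is mandatory in the schema, but the reader defaults it to
true on lenient inputs rather than failing.

The vendored XSDs are *subset schemas written for this library*: they
cover exactly the element/attribute subset the writer emits, with the
1.1 variant keeping the historical 1..n `PeptideEvidenceRef` cardinality
that 1.2 relaxed.  They are labelled `*_synthetic.xsd`; the official PSI
schemas can replace them for full structural checking.

## Controlled vocabularies

The CV engine interprets the OBO stanza subset the PSI formats rely on
(`id`, `name`, `is_a`, `is_obsolete`), with line-numbered parse errors
and explicit is_a cycle detection; closure and branch-membership queries
drive the semantic rules.  The shipped PSI-MS subset contains every term
the validator and workflows reference.  Accessions the format
documentation does not pin down — the PSM-level / peptide-level /
localization score branch roots and the proteogenomics coordinate params
— are plausible placeholders, clearly marked in the OBO remark and
remappable through `TermRegistry`, so a deployment using the full PSI-MS
CV can rebind them without code changes.  Accession matching is
case-sensitive; names are used only for diagnostics.

## Semantic validation

Generic rules are data: `(scope, MAY/SHOULD/MUST, branch roots,
cardinality)` entries loaded from JSON, mirroring the PSI "CV mapping
file" idea.  The 1.2 conditional rules are built in because they need
cross-element logic a mapping file cannot express.  All conditional rules
are MUST/error, matching the imperative language of the specification;
the one exception is PEP-4 (recomputed grouping-key consistency), which
is SHOULD/warning because readers are not obliged to recompute grouping
keys.  Spectrum-identifier uniqueness (UNIQ-1) is enforced on *every* 1.2
document, keyed on the (spectra data, spectrum id) pair — the
specification phrases it as a blanket 1.2 constraint rather than one
conditional on the consensus flag — with a config switch to disable it.
"Identical score" comparisons (XL-4, PEP-3) are exact string equality by
default; `ValidatorConfig.score_tolerance` enables a relative numeric
tolerance for files whose writers reformat numbers.  Messages carry
(rule id, level, locus, text), are ordered by document position, and a
document is valid iff no error-level message is produced.

Cross-link chains of more than two peptides are accepted as one donor
plus multiple acceptors sharing a link value; the tied-rank PSM group may
have any size ≥ 2.  Per-chain individual scores are stored as ordinary
params and not validated.

## Localization codec

The score grammar is four colon-separated fields
`MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD`; positions are '|'-joined,
sorted, duplicate-free integers in [0, len+1], with the terminus
conventions applying inside '|' lists too.  SCORE accepts any decimal
(exponent allowed) and is emitted in shortest-repr form; booleans are
read case-insensitively and emitted lowercase.  `confident_sites` keeps
only pass-threshold scores with a *single* position — a '|' list is
ambiguous by construction and never contributes, whatever its threshold
status — and maps peptide position p to protein position
`PeptideEvidence.start + p − 1` (1-based), deduplicating on
(protein, position, modification) and keeping the highest score.
Evidence without a start position is skipped with a warning.

## Peptide grouping and target–decoy q-values

Grouping keys: uppercase sequence; plus the sorted (location,
modification identity) list; plus charge.  Modification identity is the
modification's CV accession when present, else the mass delta rounded to
4 decimals — robust to files lacking identity terms.  The key string
itself is the group id, so ids are deterministic and human-readable (the
plain sequence under sequence-grouping, as the specification suggests).

A group is decoy only if **all** member PSMs map exclusively to decoy
evidence; mixed groups count as target (the conservative convention).
The best PSM score per group is max (or min, caller-supplied direction,
since score terms differ in polarity).  The FDR estimator is the simple
decoy/target ratio with q-value monotonization — no +1 correction, no
posterior modelling — chosen because it is the simplest defensible
estimator and exactly checkable against a brute-force prefix-counting
oracle, which the tests and acceptance script do on random instances.
With zero decoys all q-values are 0; an all-decoy input warns.
`apply_peptide_annotations` writes the group id and a shared q-value
string onto every member PSM, declares the flag, grouping mode and
q-value threshold on the protocol, sets `passThreshold` from the group
q-value (default threshold 0.01, the field's consensus 1% FDR), and
refuses to overwrite a document annotated under a different grouping.

## Proteogenomics

Genomic coordinates are stored 1-based inclusive in CV params (matching
mzIdentML's own start/end convention) and converted to 0-based half-open
only at BED12 export.  Accepted mappings must have sorted, disjoint
blocks, a declared exon count equal to the block count, and block
lengths summing to 3 nt per residue (coding assumption, no stop codon).
Blocks stay in ascending genomic order on the minus strand, as BED
requires.  `read_bed` inverts the export for round-trip checking; the
genome build is not representable in BED and is dropped on import.

## Synthetic fixtures

The generator is a pure function of (workflow, parameters, seed) —
identical inputs give byte-identical files.  Defaults: 20 spectra, 12
target peptides, 0.3 decoy fraction, 3 fractions in the prefractionation
case; sizes chosen so every characteristic structure (an ambiguous
localization, both termini, junction-spanning mappings, repeated PSMs
per peptide group) occurs while keeping a full test matrix under a few
seconds.  Peptides are uniform draws from the 20-letter alphabet;
decoys are sequence reversals flagged on their evidence; target and
decoy PSM scores come from Gaussians at mean 100 and 70 (sd 10), far
enough apart that q-value curves are non-degenerate but overlapping
enough that decoys can outrank weak targets.  The fixtures emulate the
*encoding*, not the physics: there are no fragment spectra, no
retention times, no realistic mass accuracy, and protein sequences are
not materialised.  Passing tests therefore demonstrate correctness of
the format handling and of the statistics on well-formed input, not
search-engine behaviour on real data.

`corrupt` plants exactly one defect per validator rule, chosen so no
other rule fires at error level (e.g. the LOC-1 defect duplicates an
index *term* rather than an index *value*, which would also break score
references).  Together the clean and defect matrices close the loop:
every rule is demonstrated both silent on valid input and triggered in
isolation.

## Numerical and degenerate-input choices

* Floats serialize via shortest `repr`, so parse∘write is exact.
* FDR ties break deterministically on group id after score.
* Empty group lists, zero-PSM results and all-decoy inputs return
  defined values (empty list / q = 1 after monotonization) with
  warnings where informative.
* The acceptance script's problem sizes (27 fixture files, 1,000 codec
  trials, 10 × 50-group FDR instances) complete in about a second and
  are stated in `scripts/acceptance.py`.

## Limitations

Streaming access for multi-GB files, conversion from pepXML or native
search-engine formats, enzyme digestion, mass recalculation, protein
inference, quantification formats and isotope-labelled cross-link pair
evidence are out of scope.  The vendored CV subset and XSD subsets are
working stand-ins, not the official artifacts.
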
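# mzidkit

A Python toolkit for **mzIdentML**, the PSI standard format for peptide and
protein identification results from mass-spectrometry proteomics.  mzidkit
reads and writes both the 1.1 and 1.2 schema series, performs
controlled-vocabulary-driven semantic validation, and implements the
computational side of the five analysis workflows that version 1.2 encodes
beyond plain database searching:

* **Modification localization** — decoding of per-site
  `MOD_INDEX:SCORE:POSITION:PASS_THRESHOLD` scores attached to PSMs
  (position 0 = N-terminus, peptide length + 1 = C-terminus, `|` = logical
  OR over indistinguishable sites) and extraction of confidently localized
  protein sites.
* **Cross-linking** — resolution of donor/acceptor peptide pairs reported
  as tied-rank PSM couples sharing a pairing identifier, with the
  convention that the donor carries the reagent mass and the acceptor a
  zero mass delta.
* **Peptide-level statistics** — collapsing redundant PSMs into peptide
  groups (by sequence; sequence + modifications; or sequence +
  modifications + charge) and estimating peptide-level q-values by target–
  decoy competition: at each score cut *k*, FDR(k) = #decoys(k) / max(1,
  #targets(k)), and q(k) = min over j ≥ k of FDR(j).
* **Proteogenomics** — decoding peptide-to-genome mappings (chromosome,
  strand, genome build, 1-based inclusive exon blocks whose lengths sum to
  3 × peptide length) and exporting them as BED12.
* **De novo / spectral library results** — the relaxed 0..n
  peptide-to-protein evidence cardinality and sequence-less library
  entries, gated on the corresponding workflow flags.

Each 1.2 file must declare its workflow through one or more flag terms in
`<SpectrumIdentificationProtocol>`; the validator activates the matching
conditional rules (`LOC-*`, `XL-*`, `PEP-*`, `PG-*`, `CARD-1`, `SPEC-1`,
`UNIQ-1`) on top of generic, data-driven CV mapping rules whose MAY /
SHOULD / MUST levels map to info / warning / error messages.  A built-in
generator (`mzidkit.synth`) produces valid fixture files for all nine
workflows and can plant single-rule defects, so the whole matrix is
testable offline.

The package ships a working subset of the PSI-MS controlled vocabulary and
a three-term XLMOD stub; full OBO releases are drop-in replacements, and
non-standardised accessions are remappable through
`mzidkit.terms.TermRegistry`.

## Worked example

Generate a peptide-level-scoring result file, inspect it, and compute
peptide q-values:

```sh
$ mzidkit synth --workflow MS:1002490 --seed 11 --n 40 -o peplevel.mzid
$ mzidkit describe peplevel.mzid
version: 1.2.0
workflows: Peptide-level scoring
SpectrumIdentificationList: 1
SpectrumIdentificationResult: 40
SpectrumIdentificationItem: 40
Peptide: 20
ProteinDetectionList: 0

$ mzidkit peptides peplevel.mzid | head -5
sil_id  group_id        is_decoy  n_psms  best_psm_score  q_value
SIL_1   FYYFDSTF        False     5       120.6459        0.0
SIL_1   SPRPKVVQPAYY    False     3       117.3508        0.0
SIL_1   ESMERNWQL       False     8       115.9981        0.0
SIL_1   YRQSLDYYWTWPMWD False     2       115.5573        0.0
```

40 PSMs collapse to non-redundant peptide groups (grouped by sequence, so
the group id *is* the sequence); `n_psms` counts the redundant PSMs behind
each group, `best_psm_score` is the best raw search-engine score among
them, and `q_value` is the peptide-level target–decoy estimate — 0.0 here
because every decoy group scores below these targets.  Validation confirms
the file is clean:

```sh
$ mzidkit validate peplevel.mzid
0 error(s)
```

The same library surface is available in Python
(`mzidkit.parse_mzid`, `validate`, `group_psms`, `peptide_fdr`,
`confident_sites`, `resolve_crosslink_pairs`, `genomic_mapping`,
`export_bed`, ...).

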
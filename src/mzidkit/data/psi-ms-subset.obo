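format-version: 1.2
data-version: subset-1.0
ontology: ms
remark: Vendored working subset of the PSI-MS controlled vocabulary: only the terms this library's validator and workflow helpers reference. Accessions not fixed by the format documentation (score branch roots, proteogenomics coordinate terms) are placeholders and are remappable through mzidkit.terms.TermRegistry. A full PSI-MS OBO release is a drop-in replacement.

[Term]
id: MS:0000000
name: Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001302
name: search parameter
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002490
name: peptide-level scoring
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002491
name: modification localization scoring
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002492
name: consensus scoring
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002493
name: sample pre-fractionation
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002494
name: cross-linking search
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1001010
name: de novo search
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002635
name: proteogenomics search
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1001031
name: spectral library search
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002495
name: no special processing
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002496
name: group PSMs by sequence
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002497
name: group PSMs by sequence with modifications
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002498
name: group PSMs by sequence with modifications and charge
is_a: MS:1001302 ! search parameter

[Term]
id: MS:1002504
name: modification index
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002509
name: cross-link donor
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002510
name: cross-link acceptor
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002511
name: cross-link spectrum identification item
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002520
name: peptide group ID
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001080
name: search type
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001083
name: ms-ms search
is_a: MS:1001080 ! search type

[Term]
id: MS:1001494
name: no threshold
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001143
name: PSM-level score
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002049
name: MS-GF:RawScore
is_a: MS:1001143 ! PSM-level score

[Term]
id: MS:1002053
name: MS-GF:EValue
is_a: MS:1001143 ! PSM-level score

[Term]
id: MS:1002358
name: peptide-level score
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001868
name: distinct peptide-level q-value
is_a: MS:1002358 ! peptide-level score

[Term]
id: MS:1002545
name: modification localization score
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002546
name: localization site probability
is_a: MS:1002545 ! modification localization score

[Term]
id: MS:1002547
name: localization delta score
is_a: MS:1002545 ! modification localization score

[Term]
id: MS:1002637
name: chromosome name
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002638
name: chromosome strand
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002644
name: genome reference version
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002640
name: peptide start positions on chromosome
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002641
name: peptide end positions on chromosome
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002642
name: peptide exon count
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1000799
name: custom unreleased software tool
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001013
name: database name
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1001062
name: Mascot MGF format
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1000774
name: multiple peak list nativeID format
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:1002551
name: spectral library entry confidence
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies

[Term]
id: MS:9999001
name: retired example term
is_a: MS:0000000 ! Proteomics Standards Initiative Mass Spectrometry Vocabularies
is_obsolete: true
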
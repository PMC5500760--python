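format-version: 1.2
data-version: stub-1.0
ontology: xlmod
remark: Three-term stub of the XLMOD cross-linking reagent vocabulary; a real XLMOD release loads through the same loader.

[Term]
id: XLMOD:00000
name: cross-linking reagent

[Term]
id: XLMOD:02001
name: DSS
is_a: XLMOD:00000 ! cross-linking reagent

[Term]
id: XLMOD:02002
name: BS3
is_a: XLMOD:00000 ! cross-linking reagent
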
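{
  "description": "Generic CV mapping rules: where CV terms may appear, from which branch, at what cardinality. Levels MAY/SHOULD/MUST map to info/warning/error.",
  "rules": [
    {
      "rule_id": "GEN-SEARCHTYPE",
      "scope": "SpectrumIdentificationProtocol/SearchType",
      "level": "MUST",
      "branch_roots": ["MS:1001080"],
      "min": 1,
      "max": 1
    },
    {
      "rule_id": "GEN-PSMSCORE",
      "scope": "SpectrumIdentificationItem",
      "level": "SHOULD",
      "branch_roots": ["MS:1001143"],
      "min": 1,
      "max": null
    },
    {
      "rule_id": "GEN-ADDPARAM",
      "scope": "SpectrumIdentificationProtocol/AdditionalSearchParams",
      "level": "MAY",
      "branch_roots": ["MS:1001302"],
      "min": 0,
      "max": null
    }
  ]
}
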
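{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "GenomicFindingsDocument",
  "type": "object",
  "required": [
    "header",
    "somatic_mutations",
    "drug_response",
    "toxicity",
    "prognosis",
    "pathways",
    "clinical_trials",
    "germline_findings",
    "provenance",
    "banner"
  ],
  "properties": {
    "header": {
      "type": "object",
      "required": ["patient_id", "cancer_type"],
      "properties": {
        "patient_id": {"type": "string"},
        "cancer_type": {"type": "string"}
      }
    },
    "somatic_mutations": {"type": "array"},
    "drug_response": {"type": "array"},
    "toxicity": {"type": "array"},
    "prognosis": {"type": "array"},
    "pathways": {"type": "array"},
    "clinical_trials": {"type": "array"},
    "germline_findings": {"type": "array"},
    "provenance": {
      "type": "object",
      "required": ["kb_version", "input_checksum"],
      "properties": {
        "kb_version": {"type": "string"},
        "input_checksum": {"type": "string"},
        "seed": {"type": ["integer", "null"]}
      }
    },
    "banner": {"type": ["string", "null"]}
  }
}
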
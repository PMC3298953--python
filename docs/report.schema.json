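{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "rescue-eval evaluation report",
  "type": "object",
  "required": ["provenance", "mtdna", "hybrid_census", "diversity", "demography"],
  "properties": {
    "provenance": {"type": "object"},
    "mtdna": {
      "type": "object",
      "properties": {
        "n_haplotypes": {"type": "integer"},
        "n_variable_sites": {"type": "integer"},
        "source_private_haplotypes": {"type": "array", "items": {"type": "string"}},
        "per_population": {"type": "array"}
      }
    },
    "hybrid_census": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n_sampled", "n_excluded", "n_hybrids", "denominator", "proportion"]
      }
    },
    "diversity": {"type": "object"},
    "demography": {"type": "object"}
  }
}
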
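{
  "type": "object",
  "required": [
    "schema_version", "metadata", "summary", "per_position", "per_read",
    "adapter_content", "duplication", "overrepresented", "warnings"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "metadata": {
      "type": "object",
      "required": ["tool", "version", "inputs", "config"],
      "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "inputs": {"type": "array"},
        "config": {"type": "object"}
      }
    },
    "summary": {
      "type": "object",
      "required": ["total_reads", "total_bases", "mean_length"],
      "properties": {
        "total_reads": {"type": "integer"},
        "total_bases": {"type": "integer"},
        "mean_length": {"type": "number"}
      }
    },
    "per_position": {
      "type": "object",
      "required": ["bin_starts", "coverage", "base_fractions",
                   "mean_phred", "phred_of_mean_error"],
      "properties": {
        "bin_starts": {"type": "array"},
        "coverage": {"type": "array"},
        "base_fractions": {"type": "array"},
        "mean_phred": {"type": "array"},
        "phred_of_mean_error": {"type": "array"}
      }
    },
    "per_read": {
      "type": "object",
      "required": ["length_hist", "gc_hist", "gc_undefined",
                   "q_hist_expected_error", "q_hist_arithmetic", "empty_reads"],
      "properties": {
        "length_hist": {"type": "object"},
        "gc_hist": {"type": "array"},
        "gc_undefined": {"type": "integer"},
        "q_hist_expected_error": {"type": "array"},
        "q_hist_arithmetic": {"type": "array"},
        "empty_reads": {"type": "integer"}
      }
    },
    "adapter_content": {
      "type": "object",
      "required": ["total_reads", "probes"],
      "properties": {
        "total_reads": {"type": "integer"},
        "probes": {"type": "object"}
      }
    },
    "insert_size": {
      "type": ["object", "null"],
      "properties": {
        "histogram": {"type": "object"},
        "undetermined": {"type": "integer"},
        "total_pairs": {"type": "integer"},
        "adapter_fraction": {"type": "number"},
        "mode": {"type": ["integer", "null"]}
      }
    },
    "duplication": {
      "type": "object",
      "required": ["remaining_fraction", "estimated_distinct",
                   "multiplicity", "depth", "exact"],
      "properties": {
        "remaining_fraction": {"type": ["number", "null"]},
        "estimated_distinct": {"type": "integer"},
        "multiplicity": {"type": "object"},
        "depth": {"type": "integer"},
        "exact": {"type": "boolean"}
      }
    },
    "overrepresented": {
      "type": "object",
      "required": ["sampled_reads", "distinct_fragments",
                   "table_saturated", "fragments"],
      "properties": {
        "sampled_reads": {"type": "integer"},
        "distinct_fragments": {"type": "integer"},
        "table_saturated": {"type": "boolean"},
        "fragments": {"type": "array"}
      }
    },
    "per_tile": {"type": ["object", "null"]},
    "ont": {"type": ["object", "null"]},
    "warnings": {"type": "array"}
  }
}
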
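{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Spectral library JSON serialization",
  "type": "object",
  "required": ["attributes", "spectra"],
  "properties": {
    "format_version": {"type": "string"},
    "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}},
    "attribute_sets": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "array",
          "items": {"$ref": "#/$defs/attribute"}
        }
      }
    },
    "clusters": {"type": "array", "items": {"$ref": "#/$defs/cluster"}},
    "spectra": {"type": "array", "items": {"$ref": "#/$defs/spectrum"}}
  },
  "$defs": {
    "attribute": {
      "type": "object",
      "required": ["accession", "name", "value"],
      "properties": {
        "accession": {"type": "string"},
        "name": {"type": "string"},
        "value": {"type": ["number", "string"]},
        "value_accession": {"type": "string"},
        "group": {"type": "integer"}
      }
    },
    "cluster": {
      "type": "object",
      "required": ["key", "attributes"],
      "properties": {
        "key": {"type": "integer"},
        "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}}
      }
    },
    "analyte": {
      "type": "object",
      "required": ["id", "attributes"],
      "properties": {
        "id": {"type": "integer"},
        "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}}
      }
    },
    "interpretation_member": {
      "type": "object",
      "required": ["analyte_id"],
      "properties": {
        "analyte_id": {"type": "integer"},
        "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}}
      }
    },
    "interpretation": {
      "type": "object",
      "required": ["id", "attributes"],
      "properties": {
        "id": {"type": "integer"},
        "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}},
        "members": {
          "type": "array",
          "items": {"$ref": "#/$defs/interpretation_member"}
        }
      }
    },
    "peak": {
      "type": "object",
      "required": ["mz", "intensity", "annotations"],
      "properties": {
        "mz": {"type": "number"},
        "intensity": {"type": "number"},
        "annotations": {"type": "array"},
        "aggregations": {"type": "array"}
      }
    },
    "spectrum": {
      "type": "object",
      "required": ["key", "attributes", "peaks"],
      "properties": {
        "key": {"type": "integer"},
        "attributes": {"type": "array", "items": {"$ref": "#/$defs/attribute"}},
        "attribute_set_refs": {"type": "array", "items": {"type": "string"}},
        "analytes": {"type": "array", "items": {"$ref": "#/$defs/analyte"}},
        "interpretations": {
          "type": "array",
          "items": {"$ref": "#/$defs/interpretation"}
        },
        "peaks": {"type": "array", "items": {"$ref": "#/$defs/peak"}}
      }
    }
  }
}
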
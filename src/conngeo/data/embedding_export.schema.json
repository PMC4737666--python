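{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "conngeo embedding export",
  "description": "Viewer-ready dump of a 3-D connectome embedding: one record per node (label, lobe, embedded coordinates, rich-club flag) plus the list of nonzero edges of the underlying connectivity matrix.",
  "type": "object",
  "required": ["format", "version", "method", "nodes", "edges"],
  "properties": {
    "format": {"type": "string", "const": "conngeo-embedding"},
    "version": {"type": "integer"},
    "method": {"type": "string"},
    "nodes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["label", "lobe", "xyz", "rich_club"],
        "properties": {
          "label": {"type": "string"},
          "lobe": {"type": "string"},
          "xyz": {"type": "array", "minItems": 3, "maxItems": 3, "items": {"type": "number"}},
          "rich_club": {"type": "boolean"}
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["i", "j", "weight"],
        "properties": {
          "i": {"type": "integer"},
          "j": {"type": "integer"},
          "weight": {"type": "number"}
        }
      }
    }
  }
}
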
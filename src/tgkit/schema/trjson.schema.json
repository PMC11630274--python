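{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "trjson.schema.json",
  "title": "trjson transmission graph",
  "description": "JSON dialect for transmission graphs: node and edge arrays with typed attributes (string, integer, float), an optional directedness flag and optional attribute definitions. Cross-object rules enforced by the tgkit validator but not expressible here: node ids unique; edge source/target reference node ids; no self-loops; at most one edge per unordered pair (undirected) or per ordered pair (directed); definition kinds agree with stored values.",
  "type": "object",
  "required": ["nodes", "edges"],
  "properties": {
    "directed": {
      "type": "boolean",
      "default": false
    },
    "definitions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "scope", "kind"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "scope": {"enum": ["node", "edge"]},
          "kind": {"enum": ["string", "integer", "float"]},
          "description": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1}
        },
        "additionalProperties": {
          "type": ["string", "integer", "number"]
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target"],
        "properties": {
          "source": {"type": "string", "minLength": 1},
          "target": {"type": "string", "minLength": 1}
        },
        "additionalProperties": {
          "type": ["string", "integer", "number"]
        }
      }
    }
  },
  "additionalProperties": false
}
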
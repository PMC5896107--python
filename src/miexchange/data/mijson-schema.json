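{
  "title": "MI-JSON, miexchange dialect, schema version 1",
  "description": "Write-only JSON serialization of binary molecular interactions for JavaScript viewer clients. The document is a flat ordered list of objects, each labelled 'interactor' or 'interaction'; interaction objects reference interactor objects by id within the same document.",
  "type": "object",
  "required": ["format", "version", "data"],
  "properties": {
    "format": {"enum": ["mi-json"]},
    "version": {"type": "string"},
    "data": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["object", "id"],
        "properties": {
          "object": {"enum": ["interactor", "interaction"]},
          "id": {"type": "string"},
          "label": {"type": "string"},
          "type": {"type": "object"},
          "organism": {"type": "object"},
          "sequence": {"type": "string"},
          "features": {"type": "array"},
          "interactorA": {"type": "string"},
          "interactorB": {"type": "string"},
          "interactionType": {"type": "object"},
          "detmethod": {"type": "object"},
          "sourceIdentifiers": {"type": "array"},
          "confidences": {"type": "array"},
          "expansion": {"type": "object"},
          "negative": {"type": "boolean"}
        }
      }
    }
  }
}
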
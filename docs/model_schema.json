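{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "difflux model dialect",
  "description": "Canonical JSON interchange format for difflux metabolic models. Files written by difflux use sorted object keys, two-space indentation and a trailing newline, so write-read-write round trips are byte-identical.",
  "type": "object",
  "required": ["metabolites", "reactions", "objective"],
  "properties": {
    "format": {"const": "difflux-model"},
    "version": {"type": "integer"},
    "id": {"type": "string"},
    "default_bound": {
      "type": "number",
      "exclusiveMinimum": 0,
      "default": 1000.0,
      "description": "Magnitude standing in for 'unbounded' fluxes."
    },
    "metabolites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "compartment": {"type": "string", "minLength": 1}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "stoichiometry", "lower_bound", "upper_bound"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "stoichiometry": {
            "type": "object",
            "additionalProperties": {"type": "number"},
            "description": "metabolite id -> signed coefficient (negative = consumed); exactly one entry for exchange reactions"
          },
          "lower_bound": {"type": "number"},
          "upper_bound": {"type": "number"},
          "subsystem": {"type": "string"},
          "is_exchange": {"type": "boolean", "default": false},
          "is_artificial": {"type": "boolean", "default": false}
        }
      }
    },
    "objective": {
      "type": "object",
      "additionalProperties": {"type": "number"},
      "description": "reaction id -> objective coefficient (the biomass objective)"
    }
  }
}
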
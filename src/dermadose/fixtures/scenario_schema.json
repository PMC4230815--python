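{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ExposureScenario",
  "type": "object",
  "required": ["chemical", "dose_per_area"],
  "properties": {
    "chemical": {"type": "string", "description": "Name of a shipped chemical record"},
    "dose_per_area": {"type": "number", "minimum": 0, "description": "ug/cm^2 per application"},
    "area": {"type": "number", "exclusiveMinimum": 0, "description": "cm^2"},
    "tau": {"type": "number", "exclusiveMinimum": 0, "default": 24, "description": "dosing interval, h"},
    "n_applications": {"type": "integer", "minimum": 1, "default": 1},
    "removal_after": {"type": ["number", "null"], "description": "h after each application at which the surface is wiped"},
    "occluded": {"type": "boolean", "default": false},
    "water_volume_per_area": {"type": "number", "minimum": 0, "default": 0, "description": "cm^3 of aqueous vehicle per cm^2 per application"},
    "duration": {"type": ["number", "null"], "description": "total simulated time, h"}
  }
}
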
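{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ahlkit screen run report",
 "type": "object",
 "required": ["command", "config", "inputs", "stages", "outputs"],
 "properties": {
  "command": {"const": "screen"},
  "config": {"type": "object"},
  "inputs": {
   "type": "object",
   "required": ["sample", "control"],
   "properties": {"sample": {"type": "string"}, "control": {"type": "string"}}
  },
  "stages": {
   "type": "object",
   "required": ["scanned", "screened", "confirmed", "candidate_masses",
                "peaks", "control_retained", "features"],
   "additionalProperties": {"type": "integer", "minimum": 0}
  },
  "clustering": {
   "type": ["object", "null"],
   "properties": {
    "k": {"type": "integer", "minimum": 1},
    "inertia": {"type": "number", "minimum": 0},
    "sizes": {"type": "array", "items": {"type": "integer", "minimum": 0}}
   }
  },
  "outputs": {"type": "object"}
 }
}
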
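{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ahlkit mine run report",
 "type": "object",
 "required": ["command", "config", "inputs", "counts", "summary", "outputs"],
 "properties": {
  "command": {"const": "mine"},
  "config": {"type": "object"},
  "inputs": {"type": "object"},
  "counts": {
   "type": "object",
   "required": ["hits_total", "hits_significant", "hits_resolved",
                "assemblies", "unique_species"],
   "additionalProperties": {"type": "integer", "minimum": 0}
  },
  "summary": {
   "type": "object",
   "required": ["synthase", "receptor"],
   "additionalProperties": {
    "type": "object",
    "required": ["family", "n_species", "median", "mean", "min", "max",
                 "n_with_at_least_one", "n_with_exactly_one"]
   }
  },
  "blast": {"type": ["object", "null"]},
  "outputs": {"type": "object"}
 }
}
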
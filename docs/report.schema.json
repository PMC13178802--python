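{
 "description": "Schema of the JSON report (shipped as docs/report.schema.json).",
 "properties": {
  "config": {
   "additionalProperties": true,
   "title": "Config",
   "type": "object"
  },
  "config_hash": {
   "title": "Config Hash",
   "type": "string"
  },
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "versions": {
   "additionalProperties": true,
   "title": "Versions",
   "type": "object"
  },
  "skipped": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Skipped",
   "type": "object"
  },
  "stoichiometry": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Stoichiometry"
  },
  "chemistry": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Chemistry"
  },
  "quantification": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Quantification"
  },
  "microbial": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Microbial"
  },
  "multivariate": {
   "anyOf": [
    {
     "additionalProperties": true,
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Multivariate"
  }
 },
 "required": [
  "config",
  "config_hash",
  "seed",
  "versions",
  "skipped"
 ],
 "title": "PipelineReport",
 "type": "object"
}
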
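{
 "$defs": {
  "AssociationRecord": {
   "properties": {
    "a": {
     "title": "A",
     "type": "integer"
    },
    "b": {
     "title": "B",
     "type": "integer"
    },
    "c": {
     "title": "C",
     "type": "integer"
    },
    "d": {
     "title": "D",
     "type": "integer"
    },
    "marker": {
     "title": "Marker",
     "type": "string"
    },
    "method": {
     "title": "Method",
     "type": "string"
    },
    "p": {
     "title": "P",
     "type": "number"
    },
    "statistic": {
     "title": "Statistic",
     "type": "number"
    },
    "variable": {
     "title": "Variable",
     "type": "string"
    }
   },
   "required": [
    "marker",
    "variable",
    "a",
    "b",
    "c",
    "d",
    "method",
    "statistic",
    "p"
   ],
   "title": "AssociationRecord",
   "type": "object"
  },
  "ClassificationBlock": {
   "properties": {
    "k_high": {
     "title": "K High",
     "type": "integer"
    },
    "k_pos": {
     "title": "K Pos",
     "type": "integer"
    },
    "patient_level": {
     "$ref": "#/$defs/StageRates"
    },
    "roc_auc": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Roc Auc"
    },
    "roc_chosen_k": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Roc Chosen K"
    },
    "sample_level": {
     "$ref": "#/$defs/StageRates"
    }
   },
   "required": [
    "sample_level",
    "patient_level",
    "k_pos",
    "k_high"
   ],
   "title": "ClassificationBlock",
   "type": "object"
  },
  "ConfigBlock": {
   "properties": {
    "config_hash": {
     "title": "Config Hash",
     "type": "string"
    },
    "seed": {
     "title": "Seed",
     "type": "integer"
    },
    "settings": {
     "additionalProperties": true,
     "title": "Settings",
     "type": "object"
    }
   },
   "required": [
    "seed",
    "config_hash",
    "settings"
   ],
   "title": "ConfigBlock",
   "type": "object"
  },
  "QuantificationBlock": {
   "properties": {
    "n_control_samples": {
     "title": "N Control Samples",
     "type": "integer"
    },
    "n_genes": {
     "title": "N Genes",
     "type": "integer"
    },
    "n_samples": {
     "title": "N Samples",
     "type": "integer"
    },
    "reference_gene": {
     "title": "Reference Gene",
     "type": "string"
    }
   },
   "required": [
    "n_genes",
    "n_samples",
    "n_control_samples",
    "reference_gene"
   ],
   "title": "QuantificationBlock",
   "type": "object"
  },
  "StageRates": {
   "properties": {
    "ctc_high_rate": {
     "title": "Ctc High Rate",
     "type": "number"
    },
    "ctc_positive_rate": {
     "title": "Ctc Positive Rate",
     "type": "number"
    },
    "hybrid_emt_rate": {
     "title": "Hybrid Emt Rate",
     "type": "number"
    },
    "n": {
     "title": "N",
     "type": "integer"
    }
   },
   "required": [
    "n",
    "ctc_positive_rate",
    "ctc_high_rate",
    "hybrid_emt_rate"
   ],
   "title": "StageRates",
   "type": "object"
  },
  "SurvivalStratum": {
   "properties": {
    "cox_p": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Cox P"
    },
    "endpoint": {
     "title": "Endpoint",
     "type": "string"
    },
    "hr": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Hr"
    },
    "logrank_p": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Logrank P"
    },
    "median_high": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Median High"
    },
    "median_low": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Median Low"
    },
    "stratum": {
     "title": "Stratum",
     "type": "string"
    }
   },
   "required": [
    "stratum",
    "endpoint"
   ],
   "title": "SurvivalStratum",
   "type": "object"
  }
 },
 "description": "Machine-readable end-of-run summary; schema shipped with the package.",
 "properties": {
  "associations": {
   "items": {
    "$ref": "#/$defs/AssociationRecord"
   },
   "title": "Associations",
   "type": "array"
  },
  "classification": {
   "$ref": "#/$defs/ClassificationBlock"
  },
  "config": {
   "$ref": "#/$defs/ConfigBlock"
  },
  "quantification": {
   "$ref": "#/$defs/QuantificationBlock"
  },
  "survival": {
   "items": {
    "$ref": "#/$defs/SurvivalStratum"
   },
   "title": "Survival",
   "type": "array"
  }
 },
 "required": [
  "config",
  "quantification",
  "classification",
  "associations",
  "survival"
 ],
 "title": "PipelineSummary",
 "type": "object"
}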
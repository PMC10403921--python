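{
  "$defs": {
    "BinProfileModel": {
      "properties": {
        "bin_width": {
          "title": "Bin Width",
          "type": "integer"
        },
        "bins": {
          "items": {
            "type": "number"
          },
          "title": "Bins",
          "type": "array"
        },
        "trim": {
          "title": "Trim",
          "type": "integer"
        }
      },
      "required": [
        "bin_width",
        "trim",
        "bins"
      ],
      "title": "BinProfileModel",
      "type": "object"
    },
    "CorrelationModel": {
      "properties": {
        "method": {
          "title": "Method",
          "type": "string"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "p_value": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "P Value"
        },
        "rho": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Rho"
        }
      },
      "required": [
        "rho",
        "p_value",
        "n",
        "method"
      ],
      "title": "CorrelationModel",
      "type": "object"
    },
    "FlagModel": {
      "properties": {
        "context": {
          "title": "Context",
          "type": "string"
        },
        "cooccurrence_odds_ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cooccurrence Odds Ratio"
        },
        "cooccurrence_p": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Cooccurrence P"
        },
        "depth": {
          "title": "Depth",
          "type": "integer"
        },
        "level": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Level"
        },
        "low_vs_adjacent": {
          "title": "Low Vs Adjacent",
          "type": "boolean"
        },
        "position": {
          "title": "Position",
          "type": "integer"
        },
        "reasons": {
          "items": {
            "type": "string"
          },
          "title": "Reasons",
          "type": "array"
        },
        "strand": {
          "title": "Strand",
          "type": "string"
        }
      },
      "required": [
        "position",
        "strand",
        "context",
        "level",
        "depth",
        "reasons",
        "low_vs_adjacent"
      ],
      "title": "FlagModel",
      "type": "object"
    },
    "StrandStatsModel": {
      "properties": {
        "hl_ratio": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Hl Ratio"
        },
        "mean_depth_H": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mean Depth H"
        },
        "mean_depth_L": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Mean Depth L"
        }
      },
      "required": [
        "mean_depth_L",
        "mean_depth_H",
        "hl_ratio"
      ],
      "title": "StrandStatsModel",
      "type": "object"
    }
  },
  "description": "Versioned aggregate report for one library.",
  "properties": {
    "bin_profile": {
      "anyOf": [
        {
          "$ref": "#/$defs/BinProfileModel"
        },
        {
          "type": "null"
        }
      ]
    },
    "conversion_rate": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Conversion Rate"
    },
    "correlation": {
      "anyOf": [
        {
          "$ref": "#/$defs/CorrelationModel"
        },
        {
          "type": "null"
        }
      ]
    },
    "flags": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/FlagModel"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "title": "Flags"
    },
    "genome": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "title": "Genome"
    },
    "n_reads_skipped": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "N Reads Skipped"
    },
    "n_reads_used": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "title": "N Reads Used"
    },
    "numt": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "title": "Numt"
    },
    "schema_version": {
      "title": "Schema Version",
      "type": "string"
    },
    "strand_stats": {
      "anyOf": [
        {
          "$ref": "#/$defs/StrandStatsModel"
        },
        {
          "type": "null"
        }
      ]
    },
    "summaries": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "title": "Summaries"
    }
  },
  "required": [
    "schema_version",
    "genome",
    "n_reads_used",
    "n_reads_skipped",
    "conversion_rate",
    "summaries",
    "strand_stats",
    "bin_profile",
    "correlation",
    "flags",
    "numt"
  ],
  "title": "QCReportModel",
  "type": "object"
}
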
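{
  "$defs": {
    "AuxiliaryEnzyme": {
      "additionalProperties": true,
      "description": "A second enzyme required for the described enzyme's activity.",
      "properties": {
        "description": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Description"
        },
        "genbank_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Genbank Id"
        },
        "name": {
          "minLength": 1,
          "title": "Name",
          "type": "string"
        },
        "uniprot_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Uniprot Id"
        }
      },
      "required": [
        "name"
      ],
      "title": "AuxiliaryEnzyme",
      "type": "object"
    },
    "ChangelogRecord": {
      "additionalProperties": true,
      "properties": {
        "date": {
          "title": "Date",
          "type": "string"
        },
        "note": {
          "title": "Note",
          "type": "string"
        },
        "version": {
          "title": "Version",
          "type": "string"
        }
      },
      "required": [
        "version",
        "date",
        "note"
      ],
      "title": "ChangelogRecord",
      "type": "object"
    },
    "EnzymeInfo": {
      "additionalProperties": true,
      "properties": {
        "auxiliary_enzymes": {
          "items": {
            "$ref": "#/$defs/AuxiliaryEnzyme"
          },
          "title": "Auxiliary Enzymes",
          "type": "array"
        },
        "description": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Description"
        },
        "genbank_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Genbank Id"
        },
        "mibig_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mibig Id"
        },
        "name": {
          "minLength": 1,
          "title": "Name",
          "type": "string"
        },
        "uniprot_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Uniprot Id"
        },
        "wikidata_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Wikidata Id"
        }
      },
      "required": [
        "name"
      ],
      "title": "EnzymeInfo",
      "type": "object"
    },
    "ExampleReaction": {
      "additionalProperties": true,
      "description": "A concrete substrate -> product(s) pair used to verify a rule.\n\nSubstrate and products must parse as SMILES; asterisk atoms (unknown\ncores / R-groups) are permitted. Optional per-example overrides of the\nproduct-matching policy let curators mark deliberately partial examples.",
      "properties": {
        "allow_subset": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Allow Subset"
        },
        "description": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Description"
        },
        "is_balanced": {
          "default": false,
          "title": "Is Balanced",
          "type": "boolean"
        },
        "products": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Products",
          "type": "array"
        },
        "stereo_strict": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Stereo Strict"
        },
        "substrate": {
          "title": "Substrate",
          "type": "string"
        }
      },
      "required": [
        "substrate",
        "products"
      ],
      "title": "ExampleReaction",
      "type": "object"
    },
    "ReactionRule": {
      "additionalProperties": true,
      "description": "A generic reaction SMARTS with its validated examples and evidence.",
      "properties": {
        "ec_number": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ec Number"
        },
        "evidence_codes": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Evidence Codes",
          "type": "array"
        },
        "examples": {
          "items": {
            "$ref": "#/$defs/ExampleReaction"
          },
          "minItems": 1,
          "title": "Examples",
          "type": "array"
        },
        "iterative": {
          "default": false,
          "title": "Iterative",
          "type": "boolean"
        },
        "references": {
          "items": {
            "type": "string"
          },
          "title": "References",
          "type": "array"
        },
        "rhea_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rhea Id"
        },
        "smarts": {
          "title": "Smarts",
          "type": "string"
        },
        "tailoring_terms": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Tailoring Terms",
          "type": "array"
        }
      },
      "required": [
        "smarts",
        "tailoring_terms",
        "examples",
        "evidence_codes"
      ],
      "title": "ReactionRule",
      "type": "object"
    }
  },
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "additionalProperties": true,
  "description": "One tailoring enzyme: identity, cross-references, reactions, provenance.",
  "properties": {
    "accession": {
      "title": "Accession",
      "type": "string"
    },
    "changelog": {
      "items": {
        "$ref": "#/$defs/ChangelogRecord"
      },
      "title": "Changelog",
      "type": "array"
    },
    "enzyme": {
      "$ref": "#/$defs/EnzymeInfo"
    },
    "reactions": {
      "items": {
        "$ref": "#/$defs/ReactionRule"
      },
      "minItems": 1,
      "title": "Reactions",
      "type": "array"
    },
    "references": {
      "items": {
        "type": "string"
      },
      "minItems": 1,
      "title": "References",
      "type": "array"
    },
    "status": {
      "default": "active",
      "title": "Status",
      "type": "string"
    }
  },
  "required": [
    "accession",
    "enzyme",
    "reactions",
    "references"
  ],
  "title": "MITE entry record",
  "type": "object"
}
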
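{
  "$defs": {
    "FieldEncoding": {
      "additionalProperties": false,
      "description": "Maps a per-bin field through a colormap (color) or range (scale).\n\nParameters\n----------\nfield : str\n    Column name on the structure, or a pseudo-field: ``\"coordinate\"``\n    (bin index within its chromosome) or ``\"chrom\"``.\nkind : {\"continuous\", \"categorical\"}\n    Continuous encodings interpolate; categorical ones cycle a palette\n    by order of first appearance.\ncolormap : str or list of RGB triples\n    For color channels.  A registry name (``\"viridis-8\"``,\n    ``\"greys-2\"``, ``\"category-12\"``) or explicit stops.\nrange : (rmin, rmax)\n    For scale channels: radii at the domain endpoints; rmin must be\n    positive (marks need positive radii).\ndomain : (lo, hi), optional\n    Field values mapped to the channel endpoints; defaults to the\n    observed min/max.  Out-of-domain values are clamped.",
      "properties": {
        "field": {
          "title": "Field",
          "type": "string"
        },
        "kind": {
          "default": "continuous",
          "enum": [
            "continuous",
            "categorical"
          ],
          "title": "Kind",
          "type": "string"
        },
        "colormap": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "items": {
                "maxItems": 3,
                "minItems": 3,
                "prefixItems": [
                  {
                    "type": "integer"
                  },
                  {
                    "type": "integer"
                  },
                  {
                    "type": "integer"
                  }
                ],
                "type": "array"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Colormap"
        },
        "range": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Range"
        },
        "domain": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Domain"
        }
      },
      "required": [
        "field"
      ],
      "title": "FieldEncoding",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Declarative visual encoding for one structure.\n\nUnknown keys are rejected (strict schema) so channel-name typos fail\nloudly instead of silently rendering defaults.",
  "properties": {
    "mark": {
      "default": "sphere",
      "enum": [
        "sphere",
        "box"
      ],
      "title": "Mark",
      "type": "string"
    },
    "color": {
      "anyOf": [
        {
          "$ref": "#/$defs/FieldEncoding"
        },
        {
          "type": "string"
        }
      ],
      "default": "#1f77b4",
      "title": "Color"
    },
    "scale": {
      "anyOf": [
        {
          "$ref": "#/$defs/FieldEncoding"
        },
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Scale"
    },
    "links": {
      "default": false,
      "title": "Links",
      "type": "boolean"
    }
  },
  "title": "ViewConfig",
  "type": "object"
}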
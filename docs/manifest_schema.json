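{
  "$defs": {
    "PatientEntry": {
      "properties": {
        "contact_table": {
          "title": "Contact Table",
          "type": "string"
        },
        "ilae_class": {
          "minimum": 1,
          "title": "Ilae Class",
          "type": "integer"
        },
        "patient_id": {
          "title": "Patient Id",
          "type": "string"
        },
        "recordings": {
          "items": {
            "$ref": "#/$defs/SegmentRef"
          },
          "minItems": 1,
          "title": "Recordings",
          "type": "array"
        }
      },
      "required": [
        "patient_id",
        "ilae_class",
        "contact_table",
        "recordings"
      ],
      "title": "PatientEntry",
      "type": "object"
    },
    "SegmentRef": {
      "description": "Pointer into a recording file: which time range of which EDF.",
      "properties": {
        "length_s": {
          "anyOf": [
            {
              "exclusiveMinimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Length S"
        },
        "offset_s": {
          "default": 0.0,
          "minimum": 0.0,
          "title": "Offset S",
          "type": "number"
        },
        "path": {
          "title": "Path",
          "type": "string"
        }
      },
      "required": [
        "path"
      ],
      "title": "SegmentRef",
      "type": "object"
    }
  },
  "properties": {
    "patients": {
      "items": {
        "$ref": "#/$defs/PatientEntry"
      },
      "title": "Patients",
      "type": "array"
    }
  },
  "required": [
    "patients"
  ],
  "title": "CohortManifest",
  "type": "object"
}
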
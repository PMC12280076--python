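{
  "$id": "smd-scorecard.schema.json",
  "title": "Synthetic Medical Data scorecard document",
  "type": "object",
  "required": ["schema_version", "sections", "footer"],
  "properties": {
    "schema_version": {"type": "string"},
    "footer": {"type": "object"},
    "sections": {
      "type": "object",
      "required": [
        "section_1_general",
        "section_2_quality",
        "section_3_task",
        "section_4_human",
        "section_5_ethics",
        "section_6_usage",
        "section_7_generation",
        "section_8_reference"
      ],
      "properties": {
        "section_1_general": {
          "type": "object",
          "required": [
            "name", "release_date", "version_history", "dataset_size",
            "dataset_modality", "dataset_provenance", "intended_use",
            "dataset_labels", "attribution_licensing", "point_of_contact"
          ]
        },
        "section_2_quality": {
          "type": "object",
          "required": [
            "congruence", "coverage", "constraint", "completeness",
            "compliance", "comprehension", "consistency"
          ],
          "properties": {
            "congruence": {"$ref": "#/definitions/criterion"},
            "coverage": {"$ref": "#/definitions/criterion"},
            "constraint": {"$ref": "#/definitions/criterion"},
            "completeness": {"$ref": "#/definitions/criterion"},
            "compliance": {"$ref": "#/definitions/criterion"},
            "comprehension": {"$ref": "#/definitions/criterion"},
            "consistency": {"$ref": "#/definitions/criterion"}
          }
        },
        "section_3_task": {
          "type": "object",
          "required": ["task_performance", "task_specific_metrics"]
        },
        "section_4_human": {
          "type": "object",
          "required": ["study_design", "reader_study_results", "observations_failure_cases"]
        },
        "section_5_ethics": {
          "type": "object",
          "required": ["privacy_anonymization", "biases", "limitations", "recommendations"]
        },
        "section_6_usage": {
          "type": "object",
          "required": [
            "repository_access", "preprocessing_requirements",
            "user_documentation", "intended_audience"
          ]
        },
        "section_7_generation": {
          "type": "object",
          "required": ["generation_method", "training_validation_process"]
        },
        "section_8_reference": {
          "type": "object",
          "required": [
            "purpose", "origin_source", "dataset_size", "clinical_population",
            "acquisition_devices", "reference_standard", "ground_truth_labels",
            "metadata", "preprocessing", "known_limitations"
          ]
        }
      }
    }
  },
  "definitions": {
    "criterion": {
      "type": "object",
      "required": ["status"],
      "properties": {
        "status": {"enum": ["computed", "not-applicable"]},
        "score": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
        "label": {"enum": ["good", "moderate", "low", null]},
        "reason": {"type": ["string", "null"]},
        "metrics": {"type": "array"}
      }
    }
  }
}
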
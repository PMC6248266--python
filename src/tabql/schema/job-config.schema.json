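{
  "$defs": {
    "DbConfig": {
      "additionalProperties": false,
      "properties": {
        "path": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Path"
        },
        "save": {
          "default": false,
          "title": "Save",
          "type": "boolean"
        },
        "existing": {
          "default": false,
          "title": "Existing",
          "type": "boolean"
        }
      },
      "title": "DbConfig",
      "type": "object"
    },
    "QueryConfig": {
      "additionalProperties": false,
      "properties": {
        "sql": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sql"
        },
        "sql_file": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sql File"
        },
        "include_header": {
          "default": true,
          "title": "Include Header",
          "type": "boolean"
        },
        "null_render": {
          "default": "",
          "title": "Null Render",
          "type": "string"
        }
      },
      "title": "QueryConfig",
      "type": "object"
    },
    "TableConfig": {
      "additionalProperties": false,
      "description": "One tabular input file and how to load it.",
      "properties": {
        "file": {
          "title": "File",
          "type": "string"
        },
        "table": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Table"
        },
        "column_names": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Column Names"
        },
        "first_row_is_header": {
          "default": false,
          "title": "First Row Is Header",
          "type": "boolean"
        },
        "load_columns": {
          "anyOf": [
            {
              "items": {
                "type": "string"
              },
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Load Columns"
        },
        "filters": {
          "default": [],
          "items": {
            "additionalProperties": true,
            "type": "object"
          },
          "title": "Filters",
          "type": "array"
        },
        "indexes": {
          "default": [],
          "items": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "title": "Indexes",
          "type": "array"
        },
        "replace": {
          "default": false,
          "title": "Replace",
          "type": "boolean"
        }
      },
      "required": [
        "file"
      ],
      "title": "TableConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "tables": {
      "default": [],
      "items": {
        "$ref": "#/$defs/TableConfig"
      },
      "title": "Tables",
      "type": "array"
    },
    "query": {
      "anyOf": [
        {
          "$ref": "#/$defs/QueryConfig"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "db": {
      "anyOf": [
        {
          "$ref": "#/$defs/DbConfig"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "title": "JobConfig",
  "type": "object"
}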
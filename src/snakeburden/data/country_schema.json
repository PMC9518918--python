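{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Country configuration for the snakebite burden model",
  "type": "object",
  "additionalProperties": false,
  "required": ["schema_version", "population", "demography", "probabilities",
               "antivenom_courses", "length_of_stay", "unit_costs", "economics"],
  "$defs": {
    "parameterValue": {
      "description": "Point estimate with plausible 95% range; a bare number means a fixed constant.",
      "oneOf": [
        {"type": "number"},
        {
          "type": "object",
          "additionalProperties": false,
          "required": ["point"],
          "properties": {
            "point": {"type": "number"},
            "low": {"type": "number"},
            "high": {"type": "number"},
            "family": {"enum": ["beta", "gamma", "lognormal",
                                 "dirichlet_share", "uniform", "fixed"]}
          }
        }
      ]
    }
  },
  "properties": {
    "schema_version": {"const": 1},
    "name": {"type": "string"},
    "population": {"type": "number", "exclusiveMinimum": 0},
    "incidence": {"$ref": "#/$defs/parameterValue",
                  "description": "Victims per 100,000 population per year; give exactly one of incidence or victims."},
    "victims": {"$ref": "#/$defs/parameterValue",
                "description": "Annual victim count; give exactly one of incidence or victims."},
    "demography": {
      "type": "object",
      "additionalProperties": false,
      "required": ["strata"],
      "properties": {
        "strata": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["sex", "age_low", "age_high", "share",
                         "mean_age_at_death"],
            "properties": {
              "sex": {"enum": ["female", "male"]},
              "age_low": {"type": "number", "minimum": 0},
              "age_high": {"type": "number", "minimum": 0},
              "share": {"$ref": "#/$defs/parameterValue"},
              "mean_age_at_death": {"type": "number", "minimum": 0}
            }
          }
        }
      }
    },
    "probabilities": {
      "type": "object",
      "additionalProperties": false,
      "required": ["conventional_first", "switch_to_conventional", "indicated",
                   "adr", "death_treated", "amputation_survivor"],
      "properties": {
        "conventional_first": {"$ref": "#/$defs/parameterValue"},
        "switch_to_conventional": {"$ref": "#/$defs/parameterValue"},
        "indicated": {"$ref": "#/$defs/parameterValue"},
        "adr": {"$ref": "#/$defs/parameterValue"},
        "death_treated": {"$ref": "#/$defs/parameterValue"},
        "amputation_survivor": {"$ref": "#/$defs/parameterValue"}
      }
    },
    "rr_death_untreated": {
      "$ref": "#/$defs/parameterValue",
      "description": "Relative risk of death without antivenom; default 2.33 (95% range 1.26-4.06), lognormal."
    },
    "antivenom_courses": {"$ref": "#/$defs/parameterValue",
                          "description": "Antivenom treatment courses available per year."},
    "length_of_stay": {
      "type": "object",
      "additionalProperties": false,
      "required": ["indicated", "not_indicated"],
      "properties": {
        "indicated": {"$ref": "#/$defs/parameterValue"},
        "not_indicated": {"$ref": "#/$defs/parameterValue"}
      }
    },
    "unit_costs": {
      "description": "Local currency units.",
      "type": "object",
      "additionalProperties": false,
      "required": ["hospital_day", "antivenom_course", "antivenom_logistics",
                   "adr_management", "amputation", "transport", "food_day"],
      "properties": {
        "hospital_day": {"$ref": "#/$defs/parameterValue"},
        "antivenom_course": {"$ref": "#/$defs/parameterValue"},
        "antivenom_logistics": {"$ref": "#/$defs/parameterValue"},
        "adr_management": {"$ref": "#/$defs/parameterValue"},
        "amputation": {"$ref": "#/$defs/parameterValue"},
        "transport": {"$ref": "#/$defs/parameterValue"},
        "food_day": {"$ref": "#/$defs/parameterValue"}
      }
    },
    "economics": {
      "type": "object",
      "additionalProperties": false,
      "required": ["exchange_rate", "gdp_per_capita", "gdp_growth"],
      "properties": {
        "exchange_rate": {"type": "number", "exclusiveMinimum": 0,
                          "description": "Local currency units per 2019 USD."},
        "gdp_per_capita": {"type": "number", "minimum": 0,
                           "description": "2019 USD."},
        "gdp_growth": {"$ref": "#/$defs/parameterValue"},
        "discount_rate": {"$ref": "#/$defs/parameterValue",
                          "description": "Default 0.03/year."},
        "retirement_age": {"type": "number", "exclusiveMinimum": 0,
                           "description": "Default 60 years."},
        "daily_income_divisor": {"type": "number", "exclusiveMinimum": 0,
                                 "description": "Days per year used to convert GDP per capita to daily income; default 365."}
      }
    }
  }
}
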
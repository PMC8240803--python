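{
  "contraceptive_use": [
    {
      "attribute": "hasType",
      "value_type": "enumerated",
      "values": ["condoms", "contraceptive injection", "contraceptive patch", "pill", "intrauterine device", "diaphragm", "sterilization"]
    },
    {
      "attribute": "hasLengthOfUse",
      "value_type": "quantity",
      "unit": "months"
    }
  ],
  "working_hours": [
    {
      "attribute": "hasHoursPerWeek",
      "value_type": "quantity",
      "unit": "hours"
    }
  ],
  "number_of_children": [
    {
      "attribute": "hasCount",
      "value_type": "quantity",
      "unit": "children"
    }
  ]
}
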
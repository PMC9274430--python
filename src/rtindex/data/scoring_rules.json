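{
  "comment": "Conditional scoring groupings for the rigor-adherence component. 'expects' is the set of groupings expected once this grouping is detected; 'expected_when' is the reverse view ('always', 'never', or a list of triggering groupings); 'affects' says which score component the grouping feeds.",
  "groupings": [
    {
      "name": "ethics1",
      "members": ["iacuc", "irb", "consent"],
      "expects": ["group_selection", "sex", "demographics", "random", "blinding", "power"],
      "expected_when": ["euthanasia"],
      "affects": "rigor"
    },
    {
      "name": "ethics2",
      "members": ["field_sample_permit"],
      "expects": ["random", "blinding", "power"],
      "expected_when": "never",
      "affects": "rigor"
    },
    {
      "name": "euthanasia",
      "members": ["euthanasia"],
      "expects": ["ethics1", "group_selection", "sex", "demographics", "random", "blinding", "power"],
      "expected_when": "never",
      "affects": "rigor"
    },
    {
      "name": "group_selection",
      "members": ["inclusion_exclusion", "attrition"],
      "expects": ["random", "blinding", "power"],
      "expected_when": ["ethics1", "euthanasia"],
      "affects": "rigor"
    },
    {
      "name": "sex",
      "members": ["sex"],
      "expects": ["random", "blinding", "power"],
      "expected_when": ["ethics1", "euthanasia", "demographics"],
      "affects": "rigor"
    },
    {
      "name": "demographics",
      "members": ["age", "weight"],
      "expects": ["sex", "random", "blinding", "power"],
      "expected_when": ["ethics1", "euthanasia"],
      "affects": "rigor"
    },
    {
      "name": "random",
      "members": ["randomization"],
      "expects": ["blinding", "power"],
      "expected_when": "always",
      "affects": "rigor"
    },
    {
      "name": "blinding",
      "members": ["blinding"],
      "expects": ["random", "power"],
      "expected_when": "always",
      "affects": "rigor"
    },
    {
      "name": "power",
      "members": ["power_analysis"],
      "expects": ["random", "blinding"],
      "expected_when": "always",
      "affects": "rigor"
    },
    {
      "name": "replication",
      "members": ["replication_statement", "n_replications", "replication_type"],
      "expects": ["random", "blinding", "power"],
      "expected_when": "never",
      "affects": "rigor"
    },
    {
      "name": "cell_line_auth",
      "members": ["cell_line_authentication", "cell_line_contamination"],
      "expects": ["sex", "random", "blinding", "power"],
      "expected_when": ["cell_lines"],
      "affects": "rigor"
    },
    {
      "name": "methods_materials_availability",
      "members": ["data_availability", "data_id", "code_availability", "code_id", "protocol_id"],
      "expects": [],
      "expected_when": "never",
      "affects": "none"
    },
    {
      "name": "cell_lines",
      "members": ["cell_line"],
      "expects": ["cell_line_auth"],
      "expected_when": "never",
      "affects": "rigor"
    },
    {
      "name": "other_resources",
      "members": ["antibody", "organism", "plasmid", "software_tool"],
      "expects": [],
      "expected_when": "never",
      "affects": "resource"
    },
    {
      "name": "misc",
      "members": ["oligonucleotide", "statistical_test"],
      "expects": [],
      "expected_when": "never",
      "affects": "none"
    }
  ],
  "always_expected": ["random", "blinding", "power"],
  "never_expected": ["ethics2", "euthanasia", "replication", "cell_lines"],
  "resource_types": ["antibody", "organism", "cell_line", "software_tool", "plasmid"]
}
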
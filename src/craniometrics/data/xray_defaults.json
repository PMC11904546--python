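[
 {"name": "MO-MO", "kind": "distance", "operands": ["MO_r", "MO_l"], "view": "frontal_pa"},
 {"name": "ECA-ECA", "kind": "distance", "operands": ["ECA_ant", "ECA_post"], "view": "lateral"},
 {"name": "Nas-Tub", "kind": "distance", "operands": ["Nas", "Tub"], "view": "lateral"},
 {"name": "EU-EU/MO-MO", "kind": "ratio",
  "operands": {"num": ["EU_r", "EU_l"], "den": ["MO_r", "MO_l"]}, "view": "frontal_pa"},
 {"name": "ECA-ECP/ECS-BA", "kind": "ratio",
  "operands": {"num": ["ECA", "ECP"], "den": ["ECS", "BA"]}, "view": "lateral"},
 {"name": "Inter-MO", "kind": "angle", "operands": ["MO_r", "Nas", "MO_l"], "view": "frontal_pa"},
 {"name": "Inter-EU", "kind": "angle", "operands": ["EU_r", "Nas", "EU_l"], "view": "frontal_pa"},
 {"name": "ECA-ECP", "kind": "distance", "operands": ["ECA", "ECP"], "view": "lateral"}
]
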
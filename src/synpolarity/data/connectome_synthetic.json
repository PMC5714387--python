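{
 "nodes": [
  "AVA",
  "AVB",
  "AVD",
  "AVE",
  "PVC",
  "DVA",
  "ASH",
  "E_b",
  "E_f"
 ],
 "syn_mean": [
  [
   0.0,
   0.6,
   12.2,
   2.6,
   5.5,
   0.75,
   4.4,
   0.0,
   0.0
  ],
  [
   2.0,
   0.0,
   0.0,
   0.4,
   1.4,
   3.0,
   0.0,
   0.0,
   0.0
  ],
  [
   1.3,
   3.4,
   0.0,
   0.7,
   1.0,
   0.5,
   0.8,
   0.0,
   0.0
  ],
  [
   1.2,
   0.0,
   1.5,
   0.0,
   1.1,
   0.35,
   2.8,
   0.0,
   0.0
  ],
  [
   4.8,
   0.5,
   0.0,
   0.5,
   0.0,
   2.4,
   2.2,
   6.0,
   0.0
  ],
  [
   0.3,
   0.0,
   0.0,
   0.0,
   0.9,
   0.0,
   0.6,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   17.0,
   0.4,
   6.2,
   7.6,
   0.0,
   0.0,
   1.9,
   0.0,
   0.0
  ],
  [
   0.0,
   1.6,
   0.0,
   0.0,
   4.0,
   1.8,
   0.25,
   0.0,
   0.0
  ]
 ],
 "syn_sd": [
  [
   0.0,
   0.25,
   2.1,
   0.6,
   1.2,
   0.25,
   1.0,
   0.0,
   0.0
  ],
  [
   0.5,
   0.0,
   0.0,
   0.2,
   0.4,
   0.7,
   0.0,
   0.0,
   0.0
  ],
  [
   0.5,
   0.8,
   0.0,
   0.3,
   0.3,
   0.2,
   0.3,
   0.0,
   0.0
  ],
  [
   0.4,
   0.0,
   0.4,
   0.0,
   0.4,
   0.15,
   0.7,
   0.0,
   0.0
  ],
  [
   1.1,
   0.2,
   0.0,
   0.2,
   0.0,
   0.6,
   0.5,
   1.2,
   0.0
  ],
  [
   0.1,
   0.0,
   0.0,
   0.0,
   0.3,
   0.0,
   0.2,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   2.8,
   0.15,
   1.4,
   1.6,
   0.0,
   0.0,
   0.5,
   0.0,
   0.0
  ],
  [
   0.0,
   0.4,
   0.0,
   0.0,
   0.9,
   0.4,
   0.1,
   0.0,
   0.0
  ]
 ],
 "gap": [
  [
   0.0,
   0.0,
   6.0,
   5.0,
   12.0,
   0.0,
   1.0,
   25.0,
   0.0
  ],
  [
   0.0,
   0.0,
   2.0,
   0.0,
   0.0,
   2.0,
   0.0,
   0.0,
   20.0
  ],
  [
   6.0,
   2.0,
   0.0,
   2.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   5.0,
   0.0,
   2.0,
   0.0,
   1.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   12.0,
   0.0,
   0.0,
   1.0,
   0.0,
   3.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   2.0,
   0.0,
   0.0,
   3.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   1.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   25.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   20.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 ],
 "fixed_excitatory": [
  [
   "E_b",
   "PVC"
  ]
 ]
}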
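{
  "edmund": [
    {"name": "FITC", "lo_nm": 539.0, "hi_nm": 556.0, "transmission": 1.0},
    {"name": "TexasRed", "lo_nm": 604.0, "hi_nm": 644.0, "transmission": 1.0},
    {"name": "Cy5", "lo_nm": 672.0, "hi_nm": 712.0, "transmission": 1.0}
  ],
  "chroma": [
    {"name": "FITC", "lo_nm": 539.0, "hi_nm": 550.0, "transmission": 1.0},
    {"name": "mCherry", "lo_nm": 593.0, "hi_nm": 667.0, "transmission": 1.0},
    {"name": "ATTO647N", "lo_nm": 669.0, "hi_nm": 741.0, "transmission": 1.0}
  ]
}
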
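{
  "u0": {"2": {"1": "1/2"}},
  "u1": {"3": {"s1": "1/6"}},
  "u2": {"4": {"s1^2": "1/24"}, "5": {"s2": "1/120"}},
  "u3": {"5": {"s1^3": "1/120"}, "6": {"s1*s2": "1/240"}, "7": {"s3": "1/5040"}}
}
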
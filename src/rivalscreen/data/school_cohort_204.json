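{
 "description": "204-child school screening cohort for simulation: 202 subjects without interocular brightness imbalance and 2 unilateral amblyopes. The first amblyope is under treatment (attenuation 0.3 log units OS, mild residual acuity loss, 20/25 OS); the second is previously undetected (attenuation 0.6 log units OS, pinhole-resistant 20/40 OS, acquired tritan defect OS).",
 "groups": [
  {"archetype": "normal", "count": 202},
  {"archetype": "amblyope", "count": 1,
   "params": {"delta": 0.3, "neural": 0.1, "eye": "OS"}},
  {"archetype": "amblyope", "count": 1,
   "params": {"delta": 0.6, "neural": 0.3, "eye": "OS", "tritan": true}}
 ]
}
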
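{
 "kind": "periodic",
 "duration": 200.0,
 "rate": 1.0,
 "seed": 0
}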
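{
 "kind": "two_state_bursting",
 "duration": 200.0,
 "burst_rate": 20.0,
 "burst_dwell": 1.0,
 "quiet_dwell": 5.0,
 "seed": 103
}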
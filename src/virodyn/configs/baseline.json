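{
 "r": 0.36,
 "a": 5.0,
 "l1": 0.48,
 "l2": 0.48,
 "e1": 10.0,
 "e2": 10.0,
 "d1": 0.4,
 "d2": 0.4,
 "tau1": 0.01,
 "tau2": 0.01
}
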
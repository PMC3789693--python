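{
 "covariate_coefs": {"batch": 0.079},
 "constant": 3.9,
 "threshold": 0.122,
 "percentile": 50.0
}
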
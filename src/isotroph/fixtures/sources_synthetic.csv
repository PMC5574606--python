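name,d13c_mean,d13c_sd,d15n_mean,d15n_sd
ice_algae,-16.1,1.2,6.8,0.8
pelagic_pom,-24.6,1.3,5.6,0.9
TEF,1.0,0.0,3.8,0.0
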
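site,d15n_sediment,d15n_sd,d13c_sediment,d13c_sd,n
NOW,7.4,0.1,-20.6,0.7,3
LS,8.3,0.3,-20.0,0.7,3
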
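# Study condition: modular (10 replications at full scale)
condition: modular
replications: 10
seed: 0
full_analyses: false
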
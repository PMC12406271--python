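# Recovery experiment: refit the single-turnover hydrolysis rate from
# simulated plate-reader traces of the ATP preset.
kind: turnover
presets: [turnover_ATP, turnover_ATP_pep65]
seeds: [1, 2, 3]
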
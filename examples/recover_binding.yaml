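# Recovery experiment: model-order selection and weighted rates for
# wild-type ATP binding observed at the lid probe.
kind: binding
presets: [wt_ATP]
seeds: [1, 2]
probe: lid
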
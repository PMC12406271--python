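# Recovery experiment: two-window (0.25 s / 250 s) analysis of the
# interface-destabilized R151A-like preset, SBDbeta-IB probe.
kind: two_window
presets: [R151A]
seeds: [1, 2]
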
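# A 2.56 ha stand for quick demonstrations (defaults emulate 25.6 ha).
width_m = 160.0
height_m = 160.0
n_transects = 24
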
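# Brown-method fine-fuel coefficients (demonstration values typical of
# Sierra Nevada mixed-conifer litterfall; replace for real analyses).
# qmd_cm: quadratic mean diameter of tallied pieces per timelag class.
angle_correction = 1.13
slope_correction = 1.0

["1h"]
qmd_cm = 0.31
specific_gravity = 0.48

["10h"]
qmd_cm = 1.37
specific_gravity = 0.48

["100h"]
qmd_cm = 4.22
specific_gravity = 0.40
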
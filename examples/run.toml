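stand_dir = "stand"
out_dir = "report"
n_sim = 99
r_max_m = 20.0
seed = 9
spatial_species = ["ABCO"]
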
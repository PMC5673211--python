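# Tungsten K fluorescence lines: fluence added to the 1-keV bin at
# line_kev when V > edge_kev, as strength*K_COEF*(V/edge-1)^K_EXP
# times the total continuum fluence.
# edge_kev=69.525 k_coef=0.31 k_exp=1.65
line_kev,strength
59,0.5
58,0.29
67,0.15
69,0.06
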
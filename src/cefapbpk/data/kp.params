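# Tissue-to-plasma partition coefficients (Kp = C_tissue / C_plasma) used in
# the PBPK models, assumed identical in mouse, rat, and human.
lung = 0.52
adipose = 0.1
muscle = 0.25
liver = 0.81
spleen = 0.41
heart = 0.23
brain = 0.11
kidney = 6.87
skin = 0.89
repro_organ = 0.5
red_marrow = 0.47
yellow_marrow = 0.25
rest_of_body = 0.5
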
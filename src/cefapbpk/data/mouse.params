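# Mouse whole-body physiology: compartment volumes (mL) and blood flows (mL/s).
# The liver flow is total hepatic (venous) outflow; the hepatic-artery inflow
# is derived as liver - spleen - gut.  gut.flow_ml_s is the portal flow of the
# splanchnic bed; the gut wall itself carries no distribution volume.
species = mouse
body_weight_kg = 0.025
haematocrit = 0.45
cardiac_output_ml_s = 0.11347
arterial_volume_ml = 0.57
venous_volume_ml = 1.13
gut.flow_ml_s = 0.02498

lung.volume_ml = 0.15833
lung.flow_ml_s = 0.11347
adipose.volume_ml = 1.91048
adipose.flow_ml_s = 0.00127
muscle.volume_ml = 9.2219
muscle.flow_ml_s = 0.01517
liver.volume_ml = 1.66355
liver.flow_ml_s = 0.03352
spleen.volume_ml = 0.10081
spleen.flow_ml_s = 0.0015
heart.volume_ml = 0.10922
heart.flow_ml_s = 0.00467
brain.volume_ml = 0.41647
brain.flow_ml_s = 0.00759
kidney.volume_ml = 0.38929
kidney.flow_ml_s = 0.0213
skin.volume_ml = 3.51582
skin.flow_ml_s = 0.01009
repro_organ.volume_ml = 0.148
repro_organ.flow_ml_s = 0.00049
red_marrow.volume_ml = 0.83204
red_marrow.flow_ml_s = 0.01355
yellow_marrow.volume_ml = 0.52449
yellow_marrow.flow_ml_s = 0.00085
rest_of_body.volume_ml = 1.3735
rest_of_body.flow_ml_s = 0.00497
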
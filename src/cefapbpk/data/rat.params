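# Rat whole-body physiology: compartment volumes (mL) and blood flows (mL/s).
species = rat
body_weight_kg = 0.31
haematocrit = 0.45
cardiac_output_ml_s = 0.9389
arterial_volume_ml = 6.944
venous_volume_ml = 14.012
gut.flow_ml_s = 0.14689

lung.volume_ml = 2.604
lung.flow_ml_s = 0.9389
adipose.volume_ml = 12.4
adipose.flow_ml_s = 0.00784
muscle.volume_ml = 151.28
muscle.flow_ml_s = 0.14695
liver.volume_ml = 12.772
liver.flow_ml_s = 0.23111
spleen.volume_ml = 0.744
spleen.flow_ml_s = 0.01175
heart.volume_ml = 1.488
heart.flow_ml_s = 0.07638
brain.volume_ml = 1.53402
brain.flow_ml_s = 0.02554
kidney.volume_ml = 4.588
kidney.flow_ml_s = 0.18019
skin.volume_ml = 49.6
skin.flow_ml_s = 0.11361
repro_organ.volume_ml = 3.1
repro_organ.flow_ml_s = 0.00979
red_marrow.volume_ml = 2.31146
red_marrow.flow_ml_s = 0.03568
yellow_marrow.volume_ml = 5.14347
yellow_marrow.flow_ml_s = 0.00794
rest_of_body.volume_ml = 30.282
rest_of_body.flow_ml_s = 0.10386
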
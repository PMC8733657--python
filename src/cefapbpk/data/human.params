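# Human whole-body physiology: compartment volumes (mL) and blood flows (mL/s).
species = human
body_weight_kg = 75.1
haematocrit = 0.45
cardiac_output_ml_s = 98.1779
arterial_volume_ml = 2148.17
venous_volume_ml = 4296.34
gut.flow_ml_s = 12.263

lung.volume_ml = 1125.5
lung.flow_ml_s = 98.1779
adipose.volume_ml = 24307.3
adipose.flow_ml_s = 8.09433
muscle.volume_ml = 25174.7
muscle.flow_ml_s = 12.5874
liver.volume_ml = 1590.1
liver.flow_ml_s = 24.3444
spleen.volume_ml = 169.973
spleen.flow_ml_s = 2.83294
heart.volume_ml = 337.26
heart.flow_ml_s = 4.10344
brain.volume_ml = 1493.16
brain.flow_ml_s = 12.6919
kidney.volume_ml = 360.411
kidney.flow_ml_s = 22.1051
skin.volume_ml = 2831.73
skin.flow_ml_s = 5.66346
repro_organ.volume_ml = 50.6174
repro_organ.flow_ml_s = 0.17716
red_marrow.volume_ml = 1106.48
red_marrow.flow_ml_s = 5.53242
yellow_marrow.volume_ml = 3075.64
yellow_marrow.flow_ml_s = 1.53782
rest_of_body.volume_ml = 2681.07
rest_of_body.flow_ml_s = 1.34054
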
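# Human fasted gastrointestinal compartments for the transit/absorption model.
# Nine serial lumen compartments: stomach, duodenum, jejunum 1-2, ileum 1-3,
# caecum, ascending colon.  Transit is first-order at 1/transit_time.
# Fluid volumes are 40% of the anatomical (pi r^2 L) segment volume, except
# the stomach, whose fasted fluid is dominated by the 250 mL of water the
# dose is taken with.  pept1_mg is the absolute hPEPT1 expression content of
# each segment; zero in stomach, caecum and colon.  passive_scale rescales
# the passive absorption rate constant 2*Peff/r per segment (reduced in the
# large intestine for the small colonic fluid/absorptive surface).
#
# transporter.global_scale is the calibrated multiplier on the carrier
# capacity Vmax, fitted once so that the fraction absorbed of an oral
# 1,126.5 mg dose is 99.9%; see cefapbpk.gut.calibrate_transporter_scale.
transporter.km_mg_l = 860.31
transporter.vmax_ug_s_mg = 0.0025
transporter.global_scale = 968.170

stomach.transit_h = 0.25
stomach.radius_cm = 10.0
stomach.length_cm = 20.0
stomach.fluid_ml = 250.0
stomach.pept1_mg = 0.0
stomach.passive_scale = 0.0

duodenum.transit_h = 0.26
duodenum.radius_cm = 1.6
duodenum.length_cm = 15.0
duodenum.fluid_ml = 48.25
duodenum.pept1_mg = 16.28
duodenum.passive_scale = 1.0

jejunum1.transit_h = 0.93
jejunum1.radius_cm = 1.45
jejunum1.length_cm = 62.0
jejunum1.fluid_ml = 163.81
jejunum1.pept1_mg = 87.84
jejunum1.passive_scale = 1.0

jejunum2.transit_h = 0.74
jejunum2.radius_cm = 1.3
jejunum2.length_cm = 62.0
jejunum2.fluid_ml = 131.67
jejunum2.pept1_mg = 73.93
jejunum2.passive_scale = 1.0

ileum1.transit_h = 0.58
ileum1.radius_cm = 1.2
ileum1.length_cm = 62.0
ileum1.fluid_ml = 112.19
ileum1.pept1_mg = 78.61
ileum1.passive_scale = 1.0

ileum2.transit_h = 0.42
ileum2.radius_cm = 1.0
ileum2.length_cm = 62.0
ileum2.fluid_ml = 77.91
ileum2.pept1_mg = 63.41
ileum2.passive_scale = 1.0

ileum3.transit_h = 0.29
ileum3.radius_cm = 0.9
ileum3.length_cm = 62.0
ileum3.fluid_ml = 63.11
ileum3.pept1_mg = 49.29
ileum3.passive_scale = 1.0

caecum.transit_h = 4.5
caecum.radius_cm = 3.5
caecum.length_cm = 13.75
caecum.fluid_ml = 211.66
caecum.pept1_mg = 0.0
caecum.passive_scale = 0.2

colon.transit_h = 13.5
colon.radius_cm = 2.5
colon.length_cm = 28.5
colon.fluid_ml = 223.84
colon.pept1_mg = 0.0
colon.passive_scale = 0.2
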
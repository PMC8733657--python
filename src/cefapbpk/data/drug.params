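# Cefadroxil physicochemical and disposition properties.
# Renal clearance is species-specific (fitted against observed plasma
# profiles); everything else is shared across species.
molecular_weight = 363.39
log_p = -0.4
pka_acid_1 = 9.71
pka_base_1 = 7.21
pka_acid_2 = 2.55
fup = 0.719
blood_plasma_ratio = 1.0
solubility_mg_ml = 12.44
solubility_ref_ph = 5.15
passive_peff_cm_s = 3.0e-6
mean_precipitation_time_s = 900
diffusion_coefficient_cm2_s = 0.75e-5
particle_density_g_ml = 1.2
renal_clearance_l_h.mouse = 0.031
renal_clearance_l_h.rat = 0.18
renal_clearance_l_h.human = 8.50
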
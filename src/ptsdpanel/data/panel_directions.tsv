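feature_id	data_type	discovery	recall	validation
70672835_SHANK2	methylation	down	up	down
75938326_C2orf3	methylation	up	up	up
75938338_C2orf3	methylation	up	up	up
AFM-LPN	protein	up	down	down
cg01208318	methylation	down	down	down
cg03405026_MLH1	methylation	up	down	down
cg03433241	methylation	up	up	down
cg04112106_CES2	methylation	up	up	down
cg15687973_PDE9A	methylation	down	down	up
cg17137457_CPT1B	methylation	down	down	down
cg20578780	methylation	down	down	down
cg26454601_MDC1	methylation	up	up	down
CPN1-IVQ	protein	down	down	down
CPN2-LLN	protein	down	up	up
CTSS-GID	protein	up	up	down
F10-NCE	protein	up	down	up
GABR	metabolite	down	up	up
gammaglutamyltyrosine	metabolite	up	up	up
heart_rate	physiological	up	up	up
hsa-miR-133a-3p	mirna	down	down	down
hsa-miR-192-5p	mirna	down	down	up
hsa-miR-424-3p	mirna	down	down	down
hsa-miR-9-5p	mirna	down	down	down
insulin	clinical_lab	up	up	up
ITIH2-VQF	protein	down	down	down
lactate_citrate	metabolite	up	up	up
mean_platelet_volume	clinical_lab	up	up	up
PTGDS-AQG	protein	down	down	down
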
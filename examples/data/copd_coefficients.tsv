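term	all_exacerbations	severe_exacerbations
intercept	0.787	-3.840
female_sex	-0.482	0.209
age_per_10y	-0.094	-0.016
oxygen_therapy_history	0.275	0.297
hospitalization_history	0.490	0.925
sgrq	0.098	0.219
fev1_litres	-0.158	-0.251
current_smoker	-0.168	-0.017
laba_user	0.157	0.466
lama_user	0.354	0.083
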
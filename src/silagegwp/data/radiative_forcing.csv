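compound,abundance_increase_ppm,forcing_increase_wm2,normalized_forcing_printed,rnrf_printed
CO2,87,1.46,0.0168,1.0
CH4,1.045,0.48,0.4593,27.4
O3,0.035,0.40,11.429,681.0
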
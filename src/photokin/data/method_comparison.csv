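added_m,uv_found_m,uv_recovery_percent,uv_rsd_percent,hplc_found_m,hplc_recovery_percent,hplc_rsd_percent
0.100e-4,0.100e-4,100.0,0.22,0.099e-4,99.0,0.52
0.200e-4,0.199e-4,99.5,0.32,0.201e-4,100.5,0.11
0.300e-4,0.301e-4,100.3,0.56,0.300e-4,100.0,0.63
0.400e-4,0.400e-4,100.0,0.48,0.402e-4,100.5,0.42
0.500e-4,0.502e-4,100.4,0.15,0.499e-4,99.8,0.39
0.600e-4,0.599e-4,99.8,0.69,0.602e-4,100.3,0.85
0.700e-4,0.701e-4,100.1,0.72,0.700e-4,100.0,0.69
0.800e-4,0.798e-4,99.8,0.22,0.801e-4,100.1,0.14
0.900e-4,0.903e-4,100.3,0.19,0.899e-4,99.9,0.36
1.000e-4,0.998e-4,99.8,0.95,1.000e-4,100.0,0.47
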
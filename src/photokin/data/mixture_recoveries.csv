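species,added_m,found_m,recovery_percent,rsd_percent
DPZ,0.100e-4,0.099e-4,99.0,0.22
DPZ,0.200e-4,0.199e-4,99.5,0.41
DPZ,0.300e-4,0.300e-4,100.0,0.36
DPZ,0.400e-4,0.401e-4,100.3,0.15
DPZ,0.500e-4,0.502e-4,100.4,0.72
DPZ,0.600e-4,0.599e-4,99.8,0.29
DPZ,0.700e-4,0.703e-4,100.4,0.11
DPZ,0.800e-4,0.802e-4,100.3,0.21
DPZ,0.900e-4,0.900e-4,100.0,0.58
RF,0.450e-4,0.448e-4,99.6,0.10
RF,0.400e-4,0.399e-4,99.8,0.19
RF,0.350e-4,0.349e-4,99.7,0.26
RF,0.300e-4,0.299e-4,99.7,0.41
RF,0.250e-4,0.251e-4,100.4,0.62
RF,0.200e-4,0.201e-4,100.5,0.74
RF,0.150e-4,0.152e-4,101.3,0.63
RF,0.100e-4,0.100e-4,100.0,0.82
RF,0.050e-4,0.051e-4,102.0,0.14
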
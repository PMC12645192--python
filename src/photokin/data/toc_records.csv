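label,toc_before_ppb,ic_before_ppb,tc_before_ppb,toc_after_ppb,ic_after_ppb,tc_after_ppb
DPZ,228,697,925,63.1,821.9,885
RF,323,692,1015,24.6,775.4,800
DPZ-RF,696,924,1620,421.0,699.0,1120
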
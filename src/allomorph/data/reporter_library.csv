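reporter,residue_number,state,delta_HN_ppm,delta_N_ppm,delta_CB_ppm
I84,84,NAC_III,7.00,,
I84,84,NAC_III_t,7.17,,
P146,146,cis,,,35.0
P146,146,trans,,,32.0
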
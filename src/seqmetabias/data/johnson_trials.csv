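study_id,effect,n_treat,n_control,n_eff,s2,df
1,0.86,,,61.30,19.94,60
2,,,,81.06,24.96,80
3,,,,69.24,8.56,68
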
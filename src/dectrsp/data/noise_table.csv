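# Image noise (standard deviation in a central circle, 2.8 cm diameter; for
# the AED Head phantom a 1 cm circle inside the central solid-water insert)
# of the Zeff, RED, and RSP maps, per phantom/SFOV acquisition and dose
# (CTDIvol, mGy). key = <preset>_<ctdi>.
key,preset,phantom,sfov,diameter_cm,ctdi_mgy,sigma_zeff,sigma_red,sigma_rsp
aed_body_18.85,aed_body,Advanced Electron Density Body,body,34.6,18.85,0.636,0.023,0.018
aed_head_18.85,aed_head,Advanced Electron Density Head,body,20,18.85,0.153,0.008,0.008
aed_head_82.77,aed_head,Advanced Electron Density Head,head,20,82.77,0.087,0.004,0.004
model467_14.55,model467,Model 467,body,33,14.55,0.496,0.021,0.018
model467_82.77,model467,Model 467,head,33,82.77,0.223,0.011,0.010
george_body_18.85,george_body,George Body,body,27,18.85,0.382,0.010,0.007
george_head_18.85,george_head,George Head,body,18,18.85,0.240,0.007,0.006
george_head_82.77,george_head,George Head,head,18,82.77,0.028,0.003,0.003
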
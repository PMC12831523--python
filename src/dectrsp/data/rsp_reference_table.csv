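# Per-insert RSP reference values and DECT ROI measurements, per phantom and
# scanning field of view (SFOV). red_ref/zeff_ref/rsp_ref(+sd) are the
# reference values (manufacturer-corrected RED, Mayneord Zeff, beam-measured
# RSP); rsp_mean_* are the DECT ROI means with their residuals
# (ROI mean - reference) and percent errors. Empty Head columns: phantom not
# rescanned with the Head SFOV. material links to reference_materials.csv.
preset,phantom,plug,material,red_ref,zeff_ref,rsp_ref,rsp_ref_sd,rsp_mean_head,residual_head,pe_head,rsp_mean_body,residual_body,pe_body
model467,Model 467,Adipose,Gammex Adipose,0.93,6.14,0.939,0.003,0.938,0.000,-0.02,0.935,-0.003,-0.33
model467,Model 467,B-200,Gammex B-200,1.10,10.11,1.108,0.003,1.098,-0.011,-0.90,1.097,-0.012,-1.07
model467,Model 467,Brain,Gammex Brain,1.04,7.40,1.069,0.003,1.036,-0.034,-3.15,1.031,-0.038,-3.55
model467,Model 467,Breast,Gammex Breast,0.96,6.82,0.976,0.003,0.972,-0.004,-0.46,0.961,-0.015,-1.55
model467,Model 467,CB2-30%,Gammex CB2-30%,1.28,10.78,1.267,0.002,1.255,-0.012,-0.94,1.251,-0.017,-1.31
model467,Model 467,CB2-50%,Gammex CB2-50%,1.47,12.40,1.427,0.002,1.429,0.002,0.14,1.414,-0.013,-0.89
model467,Model 467,Cortical bone,Gammex Cortical Bone,1.69,13.53,1.616,0.005,1.630,0.014,0.89,1.623,0.008,0.46
model467,Model 467,Inner bone,Gammex Inner Bone,1.09,10.11,1.090,0.003,1.083,-0.007,-0.66,1.077,-0.013,-1.17
model467,Model 467,Liver,Gammex Liver,1.06,7.59,1.080,0.003,1.067,-0.013,-1.17,1.061,-0.019,-1.76
model467,Model 467,LN-300,Gammex LN-300,0.29,7.61,0.263,0.010,0.282,0.019,7.07,0.276,0.013,4.90
model467,Model 467,LN-450,Gammex LN-450,0.44,7.58,0.459,0.006,0.463,0.004,0.85,0.472,0.013,2.86
model467,Model 467,Solid Water 1,Gammex Solid Water,0.99,7.59,1.005,0.003,0.997,-0.008,-0.83,0.991,-0.015,-1.48
model467,Model 467,Solid Water 2,Gammex Solid Water,0.99,7.59,1.005,0.003,0.998,-0.008,-0.79,0.996,-0.010,-0.95
model467,Model 467,Solid Water 3,Gammex Solid Water,0.99,7.59,1.005,0.003,0.999,-0.006,-0.63,0.992,-0.014,-1.34
model467,Model 467,Solid Water 4,Gammex Solid Water,0.99,7.59,1.005,0.003,1.001,-0.005,-0.49,0.989,-0.016,-1.61
model467,Model 467,True Water,True Water,1.00,7.42,1.000,0.000,0.998,-0.002,-0.19,0.993,-0.007,-0.72
george_body,George Body,Brain,George Brain,1.039,7.48,1.040,0.003,,,,1.044,0.004,0.36
george_body,George Body,Cortical bone,George Cortical Bone,1.635,13.06,1.555,0.004,,,,1.526,-0.029,-1.89
george_body,George Body,Enamel,George Enamel,1.875,17.20,1.755,0.004,,,,1.792,0.037,2.10
george_body,George Body,Spinal cord,George Spinal Cord,1.032,7.47,1.040,0.003,,,,1.042,0.002,0.21
george_body,George Body,Spinal disk,George Spinal Disk,1.058,7.96,1.070,0.003,,,,1.087,0.017,1.63
george_body,George Body,Trabecular bone,George Trabecular Bone,1.100,9.12,1.100,0.003,,,,1.081,-0.019,-1.70
george_head,George Head,Brain,George Brain,1.039,7.48,1.040,0.003,1.045,0.005,0.46,1.046,0.006,0.56
george_head,George Head,Cortical bone,George Cortical Bone,1.635,13.06,1.555,0.004,1.527,-0.028,-1.78,1.547,-0.008,-0.55
george_head,George Head,Dentin,George Dentin,1.555,14.00,1.495,0.004,1.472,-0.024,-1.57,1.489,-0.006,-0.42
george_head,George Head,Enamel,George Enamel,1.875,17.20,1.755,0.004,1.790,0.035,1.98,1.812,0.057,3.26
george_head,George Head,Sinus,George Sinus,0.200,7.42,0.200,0.005,0.225,0.025,12.40,0.213,0.013,6.30
george_head,George Head,Spinal cord,George Spinal Cord,1.032,7.47,1.040,0.003,1.043,0.003,0.33,1.044,0.004,0.42
george_head,George Head,Spinal disk,George Spinal Disk,1.058,7.96,1.070,0.003,1.087,0.017,1.57,1.089,0.019,1.74
george_head,George Head,Trabecular bone,George Trabecular Bone,1.100,9.12,1.100,0.003,1.081,-0.019,-1.76,1.088,-0.012,-1.12
aed_body,Advanced Electron Density Body,Adipose,AED Adipose,0.94,6.61,0.960,0.002,,,,0.956,-0.004,-0.40
aed_body,Advanced Electron Density Body,Brain,AED Brain,1.02,7.63,1.028,0.002,,,,1.027,-0.001,-0.11
aed_body,Advanced Electron Density Body,Breast,AED Breast,0.97,6.92,0.981,0.002,,,,0.977,-0.004,-0.40
aed_body,Advanced Electron Density Body,CaCO3 30%,AED CaCO3 30%,1.27,10.78,1.261,0.002,,,,1.260,0.000,-0.03
aed_body,Advanced Electron Density Body,CaCO3 50%,AED CaCO3 50%,1.46,12.40,1.451,0.002,,,,1.437,-0.013,-0.92
aed_body,Advanced Electron Density Body,Cortical bone,AED Cortical Bone,1.78,13.63,1.699,0.002,,,,1.721,0.022,1.28
aed_body,Advanced Electron Density Body,Inner bone,AED Inner Bone,1.16,10.39,1.143,0.002,,,,1.148,0.005,0.45
aed_body,Advanced Electron Density Body,Liver,AED Liver,1.05,7.61,1.059,0.002,,,,1.054,-0.004,-0.43
aed_body,Advanced Electron Density Body,LN-300,AED LN-300,0.28,7.61,0.289,0.001,,,,0.292,0.003,1.11
aed_body,Advanced Electron Density Body,LN-450,AED LN-450,0.44,7.58,0.477,0.001,,,,0.487,0.010,2.14
aed_body,Advanced Electron Density Body,Solid Water 1,AED Solid Water,1.00,7.45,1.002,0.002,,,,0.997,-0.005,-0.48
aed_body,Advanced Electron Density Body,Solid Water 2,AED Solid Water,1.00,7.45,1.002,0.002,,,,0.996,-0.006,-0.54
aed_body,Advanced Electron Density Body,Solid Water 3,AED Solid Water,1.00,7.45,1.002,0.002,,,,0.996,-0.006,-0.60
aed_body,Advanced Electron Density Body,Solid Water 4,AED Solid Water,1.00,7.45,1.002,0.002,,,,0.996,-0.005,-0.53
aed_body,Advanced Electron Density Body,True Water 1,True Water,1.00,7.42,1.000,0.000,,,,1.004,0.004,0.35
aed_body,Advanced Electron Density Body,True Water 2,True Water,1.00,7.42,1.000,0.000,,,,1.003,0.003,0.27
aed_head,Advanced Electron Density Head,Adipose,AED Adipose,0.94,6.61,0.960,0.002,0.955,-0.005,-0.51,0.956,-0.004,-0.46
aed_head,Advanced Electron Density Head,Brain,AED Brain,1.02,7.63,1.028,0.002,1.028,0.000,0.00,1.029,0.001,0.11
aed_head,Advanced Electron Density Head,Breast,AED Breast,0.97,6.92,0.981,0.002,0.975,-0.006,-0.60,0.976,-0.005,-0.49
aed_head,Advanced Electron Density Head,CaCO3 30%,AED CaCO3 30%,1.27,10.78,1.261,0.002,1.255,-0.005,-0.42,1.258,-0.002,-0.18
aed_head,Advanced Electron Density Head,CaCO3 50%,AED CaCO3 50%,1.46,12.40,1.451,0.002,1.429,-0.022,-1.50,1.432,-0.018,-1.26
aed_head,Advanced Electron Density Head,Cortical bone,AED Cortical Bone,1.78,13.63,1.699,0.002,1.720,0.021,1.27,1.722,0.023,1.33
aed_head,Advanced Electron Density Head,Solid Water 1,AED Solid Water,1.00,7.45,1.002,0.002,1.000,-0.002,-0.16,0.998,-0.003,-0.33
aed_head,Advanced Electron Density Head,Solid Water 2,AED Solid Water,1.00,7.45,1.002,0.002,0.997,-0.005,-0.48,0.998,-0.004,-0.38
aed_head,Advanced Electron Density Head,Solid Water 3,AED Solid Water,1.00,7.45,1.002,0.002,0.999,-0.003,-0.27,0.999,-0.003,-0.30
aed_head,Advanced Electron Density Head,True Water 1,True Water,1.00,7.42,1.000,0.000,1.004,0.004,0.36,1.004,0.004,0.37
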
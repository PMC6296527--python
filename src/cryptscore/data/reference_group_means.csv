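# Published group-level geometric means (OD units) from the source randomized
# trial of calcium and vitamin D supplementation in colorectal adenoma patients:
# one row per variable x zone x contrast x role, baseline and 1-year follow-up,
# with the reported relative and absolute treatment effects on treated rows.
variable,zone,contrast,role,n_baseline,gm_baseline,n_followup,gm_followup,relative_reported,abs_reported
mib1,whole,vitD_vs_noD,reference,51,1153,51,1269,,
mib1,whole,vitD_vs_noD,treated,52,1196,53,1273,0.97,-39.3
mib1,whole,ca_vs_noCa,reference,29,1315,29,1259,,
mib1,whole,ca_vs_noCa,treated,32,1216,33,1236,1.06,74.8
mib1,whole,caD_vs_ca,reference,39,1068,39,1236,,
mib1,whole,caD_vs_ca,treated,35,1185,36,1314,0.96,-39.8
mib1,upper40,vitD_vs_noD,reference,51,51.3,51,55.3,,
mib1,upper40,vitD_vs_noD,treated,52,43.2,53,38.9,0.84,-8.3
mib1,upper40,ca_vs_noCa,reference,29,55.1,29,41.0,,
mib1,upper40,ca_vs_noCa,treated,32,43.8,33,42.2,1.29,12.5
mib1,upper40,caD_vs_ca,reference,39,44.6,39,55.8,,
mib1,upper40,caD_vs_ca,treated,35,43.9,36,41.5,0.76,-13.6
mib1,phi_h,vitD_vs_noD,reference,51,0.045,51,0.044,,
mib1,phi_h,vitD_vs_noD,treated,52,0.036,53,0.031,0.86,0.004
mib1,phi_h,ca_vs_noCa,reference,29,0.042,29,0.033,,
mib1,phi_h,ca_vs_noCa,treated,32,0.036,33,0.034,1.22,0.007
mib1,phi_h,caD_vs_ca,reference,39,0.042,39,0.045,,
mib1,phi_h,caD_vs_ca,treated,35,0.037,36,0.032,0.79,0.008
p21,whole,vitD_vs_noD,reference,51,599.4,51,495.1,,
p21,whole,vitD_vs_noD,treated,53,603.2,53,540.4,1.08,41.5
p21,whole,ca_vs_noCa,reference,29,631.1,29,491.9,,
p21,whole,ca_vs_noCa,treated,33,652.3,33,585.9,1.15,72.8
p21,whole,caD_vs_ca,reference,39,580.0,39,464.4,,
p21,whole,caD_vs_ca,treated,36,580.1,36,585.2,1.26,120.7
p21,upper40,vitD_vs_noD,reference,51,318.9,51,253.1,,
p21,upper40,vitD_vs_noD,treated,53,316.9,53,281.4,1.12,30.3
p21,upper40,ca_vs_noCa,reference,29,344.7,29,248.6,,
p21,upper40,ca_vs_noCa,treated,33,357.5,33,317.0,1.23,55.6
p21,upper40,caD_vs_ca,reference,39,302.5,39,238.4,,
p21,upper40,caD_vs_ca,treated,36,303.8,36,309.3,1.29,69.6
p21_mib1,whole,vitD_vs_noD,reference,51,0.52,51,0.39,,
p21_mib1,whole,vitD_vs_noD,treated,53,0.50,53,0.42,1.13,0.05
p21_mib1,whole,ca_vs_noCa,reference,29,0.50,29,0.40,,
p21_mib1,whole,ca_vs_noCa,treated,33,0.54,33,0.42,0.95,-0.02
p21_mib1,whole,caD_vs_ca,reference,39,0.54,39,0.38,,
p21_mib1,whole,caD_vs_ca,treated,36,0.49,36,0.45,1.33,0.12
p21_mib1,upper40,vitD_vs_noD,reference,51,6.21,51,4.57,,
p21_mib1,upper40,vitD_vs_noD,treated,53,7.25,53,7.24,1.36,1.63
p21_mib1,upper40,ca_vs_noCa,reference,29,6.54,29,6.34,,
p21_mib1,upper40,ca_vs_noCa,treated,33,6.76,33,5.33,0.81,-1.23
p21_mib1,upper40,caD_vs_ca,reference,39,6.78,39,4.27,,
p21_mib1,upper40,caD_vs_ca,treated,36,6.81,36,7.45,1.73,3.15
bax,whole,vitD_vs_noD,reference,51,275.6,51,381.9,,
bax,whole,vitD_vs_noD,treated,53,296.2,53,397.3,0.97,-5.2
bax,whole,ca_vs_noCa,reference,29,289.3,29,409.9,,
bax,whole,ca_vs_noCa,treated,33,295.1,33,345.6,0.83,-70.1
bax,whole,caD_vs_ca,reference,39,292.6,39,350.9,,
bax,whole,caD_vs_ca,treated,36,270.7,36,410.7,1.27,81.8
bcl2,whole,vitD_vs_noD,reference,51,669.8,51,706.7,,
bcl2,whole,vitD_vs_noD,treated,52,694.4,52,752.4,1.03,21.1
bcl2,whole,ca_vs_noCa,reference,29,631.8,29,693.6,,
bcl2,whole,ca_vs_noCa,treated,32,724.8,32,701.7,0.88,-84.9
bcl2,whole,caD_vs_ca,reference,39,671.8,39,688.1,,
bcl2,whole,caD_vs_ca,treated,35,717.5,35,787.5,1.07,53.7
bax_bcl2,whole,vitD_vs_noD,reference,51,0.41,51,0.54,,
bax_bcl2,whole,vitD_vs_noD,treated,52,0.44,52,0.53,0.92,-0.04
bax_bcl2,whole,ca_vs_noCa,reference,29,0.45,29,0.58,,
bax_bcl2,whole,ca_vs_noCa,treated,32,0.46,32,0.53,0.90,-0.06
bax_bcl2,whole,caD_vs_ca,reference,39,0.44,39,0.51,,
bax_bcl2,whole,caD_vs_ca,treated,35,0.39,35,0.52,1.15,0.06
bax_mib1,whole,vitD_vs_noD,reference,51,0.24,51,0.30,,
bax_mib1,whole,vitD_vs_noD,treated,53,0.25,53,0.31,1.01,0.00
bax_mib1,whole,ca_vs_noCa,reference,29,0.22,29,0.33,,
bax_mib1,whole,ca_vs_noCa,treated,33,0.26,33,0.29,0.75,-0.08
bax_mib1,whole,caD_vs_ca,reference,39,0.27,39,0.28,,
bax_mib1,whole,caD_vs_ca,treated,36,0.23,36,0.31,1.33,0.07
bax_mib1,upper40,vitD_vs_noD,reference,51,1.34,51,2.01,,
bax_mib1,upper40,vitD_vs_noD,treated,53,1.87,53,2.94,1.04,0.40
bax_mib1,upper40,ca_vs_noCa,reference,29,1.36,29,2.97,,
bax_mib1,upper40,ca_vs_noCa,treated,33,1.60,33,2.07,0.59,-1.14
bax_mib1,upper40,caD_vs_ca,reference,39,1.73,39,1.86,,
bax_mib1,upper40,caD_vs_ca,treated,36,1.65,36,2.80,1.58,1.02
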
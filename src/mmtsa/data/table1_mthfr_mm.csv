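study_id,year,country,ethnicity,method,control_source,case_cc,case_ct,case_tt,ctrl_cc,ctrl_ct,ctrl_tt
Jiang,2014,China,Asia,Microarray,HB,9,11,10,72,66,19
Martino,2014,Mixed,Caucasian,TaqMan assay,"HB, PB",554,525,185,767,787,243
Lima,2008,Brazil,Caucasian,PCR-RFLP,PB,52,57,14,92,79,17
Moon,2007,Korea,Asia,TaqMan assay,PB,57,103,36,144,196,94
Kim,2007,Korea,Asia,PCR-RFLP/Real-time PCR,PB,58,80,35,540,863,297
Chiusolo,2006,Italy,Caucasian,PCR-RFLP,PB,31,44,25,36,45,19
Lincz,2003,Australia,Caucasian,PCR-RFLP,PB,38,44,8,145,133,21
González-Fraile,2002,Spain,Caucasian,PCR-RFLP,PB,31,48,11,38,32,9
González Ordóñez,2000,Spain,Caucasian,PCR-RFLP,Unknown,5,17,4,92,88,20
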
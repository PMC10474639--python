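patient_id,age,sex,charlson_ge2,crp,ldh,log_ddimer,lymphocytes,wave,treatment_day,history,hospital_acquired,readmission,pre_treatment
1,60,1,0,50,300,6.6,1000,1,2,0:1;20:3,False,False,False
2,60,0,0,50,300,6.6,1000,1,4,0:1;30:4,False,False,False
3,60,1,0,50,300,6.6,1000,1,1,0:1;10:4,False,False,False
4,60,1,0,50,300,6.6,1000,1,0,0:1;15:5,False,False,False
5,60,0,0,50,300,6.6,1000,1,,0:1;10:2;25:3,False,False,False
6,60,1,0,50,300,6.6,1000,1,,0:1;40:4,False,False,False
7,60,0,0,50,300,6.6,1000,1,8,0:1;3:3,False,False,False
8,60,1,0,50,300,6.6,1000,1,,0:1,False,False,False
9,60,0,0,50,300,6.6,1000,1,7,0:1;30:4,False,False,False
10,60,1,0,50,300,6.6,1000,1,,0:1;5:3,False,False,False
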
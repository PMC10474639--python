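patient_id,age,sex,charlson_ge2,crp,ldh,log_ddimer,lymphocytes,wave,treatment_day,history,hospital_acquired,readmission,pre_treatment
0,65.23197285388056,0,0,481.91973299301424,768.3016304258206,6.682638314722523,1556.5674031174685,1,2.0,0:1;6:4,False,False,False
1,70.15666099588208,1,0,25.09812473096289,223.64964146958397,6.044316319553704,625.6703079075471,3,0.0,0:1;11:3,False,True,False
2,77.07566731728149,0,0,61.75468693973743,237.30101196759716,6.69469734833295,2202.9851470700187,1,,0:1;10:4,False,False,False
3,67.93006636809896,0,1,63.73273602562049,359.19479978687093,6.7393736646454,700.9965407209074,1,,0:1;17:5,False,False,False
4,55.868204714140475,1,0,56.01358081521417,389.8774316415758,7.621722418350741,2426.6569643944185,1,0.0,0:1;4:4,False,False,False
5,80.16464168383136,1,1,17.643916884941437,261.75301378750146,6.6328061129317,318.4644488038774,2,0.0,0:1;8:5,False,False,False
6,74.63522319013045,1,1,104.67064664433589,424.45748252784443,7.219272874950934,1201.9678984234781,1,3.0,0:1;5:4,False,False,False
7,40.404154516648425,1,0,231.2164965368009,214.3130461955202,5.1536812280978035,1819.4511693960628,1,,0:1;1:4,False,False,False
8,66.92953956813383,0,1,16.698388991697204,427.9891411927796,5.429495336770749,295.2269683214896,2,0.0,0:1;3:3,False,False,False
9,71.45110717428581,0,0,77.30668579932934,431.6136127566817,4.959625177826891,161.40591697128704,1,,0:1;4:2;6:3,False,False,False
10,67.46397147102435,0,1,51.98419024506033,289.994704670144,7.230374017259438,1146.4545856439497,1,1.0,0:1;1:4,False,False,False
11,68.18750217064101,1,1,44.56520748436804,158.10846308485338,6.3699932324028214,1279.2027655803975,1,,0:1;17:5,False,False,False
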
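sample_id,station,water_type,longitude_e,latitude_n,sampling_date,depth_m,temperature_c,salinity,ph,iso_conc_cl_ng_l,iso_conc_total_ipl_ng_l,iso_conc_phospho_ipl_ng_l,tex86_cl,tex86_total_ipl,tex86_phospho_ipl,ri2_cl,ri2_total_ipl,ri2_phospho_ipl,archaea_16s_copies_l,mgii_16s_copies_l
R1_sur,R1,river,113°34.249′,22°52.647′,06/21/2011,1.5,29.7,0.2,7.25,188.6,201.5,16.7,0.59,0.50,0.57,0.19,0.15,0.12,2.1E+09,3.0E+05
R1_bott,R1,river,113°34.249′,22°52.647′,06/21/2011,6.0,29.6,0.2,7.25,221.3,128.1,8.9,0.60,0.56,0.54,0.16,0.12,0.15,3.6E+08,1.2E+03
R2_sur,R2,river,113°36.680′,22°56.338′,06/21/2011,1.5,29.0,0.1,6.95,64.8,82.5,6.8,0.56,0.42,0.49,0.16,0.15,0.11,–,–
R2_bott,R2,river,113°36.680′,22°56.338′,06/21/2011,6.0,29.0,0.1,6.90,266.6,426.5,27.9,0.60,0.45,0.38,0.14,0.10,0.12,–,–
R3,R3,river,113°28.726′,23°04.339′,06/22/2011,1.5,29.4,0.1,7.46,79.8,150.2,8.0,0.57,0.41,0.38,0.07,0.09,0.14,–,–
R4,R4,river,113°33.507′,22°58.409′,06/22/2011,1.5,29.6,0.2,7.28,19.1,30.6,3.3,0.63,0.57,0.37,0.26,0.13,0.20,–,–
R5,R5,river,113°29.941′,22°53.588′,06/22/2011,1.5,28.5,0.1,7.28,20.0,30.4,2.0,0.61,0.48,0.35,0.37,0.40,0.34,–,–
R6,R6,river,113°33.088′,22°44.811′,06/22/2011,1.5,27.8,0.1,6.92,49.1,21.8,1.2,0.62,0.68,0.53,0.15,0.19,0.25,–,–
M_lt,M,mixing,113°45.098′,22°27.206′,06/18/2011,1.5,–,–,–,25.9,105.0,2.4,0.66,0.55,0.53,0.52,0.47,0.43,2.0E+07,6.1E+06
M_st,M,mixing,113°45.098′,22°27.206′,06/18/2011,1.5,–,–,–,35.3,97.3,1.4,0.58,0.65,0.60,0.36,0.61,0.61,1.3E+09,3.1E+08
M_ht,M,mixing,113°45.098′,22°27.206′,06/18/2011,1.5,–,–,–,21.9,86.8,2.8,0.59,0.56,0.55,0.43,0.46,0.38,6.9E+07,1.2E+07
M_sur,M,mixing,113°45.098′,22°27.206′,06/18/2011,1.5,28.7,11.1,8.03,18.9,67.0,1.9,0.58,0.60,0.63,0.36,0.44,0.65,1.5E+09,5.7E+08
M_mid,M,mixing,113°45.098′,22°27.206′,06/18/2011,5.0,28.3,15.6,7.93,102.6,73.4,5.2,0.61,0.64,0.59,0.35,0.47,0.36,6.0E+09,7.9E+08
M_bott,M,mixing,113°45.098′,22°27.206′,06/18/2011,9.0,27.6,23.0,7.89,107.4,76.7,6.0,0.56,0.60,0.58,0.30,0.42,0.38,5.1E+09,1.6E+09
S_sur,S,sea,113°70.448′,22°05.165′,06/15/2011,1.5,29.6,29.5,8.63,1.1,0.7,0.1,0.52,0.65,0.58,0.28,0.39,0.22,1.0E+05,4.8E+03
S_subs,S,sea,113°70.448′,22°05.165′,06/15/2011,5.0,29.5,29.7,8.64,2.1,1.1,0.1,0.56,0.63,0.58,0.27,0.33,0.24,3.1E+06,5.3E+05
S_mid,S,sea,113°70.448′,22°05.165′,06/15/2011,10.0,28.6,31.7,8.45,12.6,13.5,0.6,0.49,0.55,0.50,0.20,0.24,0.23,9.8E+04,4.4E+03
S_bott,S,sea,113°70.448′,22°05.165′,06/15/2011,18.0,25.4,33.7,7.92,21.4,9.6,0.7,0.53,0.59,0.49,0.20,0.39,0.21,1.3E+08,1.9E+07
Sedi-R1,R1,sediment,113°34.249′,22°52.647′,06/21/2011,8.0,–,–,7.46,461.8,142.8,9.5,0.58,0.37,0.30,0.27,0.38,0.41,–,–
Sedi-R2,R2,sediment,113°36.680′,22°56.338′,06/21/2011,7.0,–,–,7.68,687.5,289.2,17.0,0.56,0.35,0.31,0.23,0.22,0.26,–,–
Sedi-R3,R3,sediment,113°28.726′,23°04.339′,06/22/2011,9.0,–,–,7.29,800.3,233.5,19.6,0.57,0.43,0.36,0.15,0.23,0.30,–,–
Sedi-R4,R4,sediment,113°33.507′,22°58.409′,06/22/2011,7.0,–,–,7.50,881.0,149.7,9.7,0.58,0.51,0.38,0.33,0.75,0.62,–,–
Sedi-R5,R5,sediment,113°29.941′,22°53.588′,06/22/2011,8.0,–,–,7.58,621.7,84.2,7.3,0.62,0.52,0.37,0.33,0.66,0.43,–,–
Sedi-R6,R6,sediment,113°33.088′,22°44.811′,06/22/2011,8.0,–,–,7.66,120.2,103.8,6.2,0.67,0.35,0.42,0.42,0.65,0.74,–,–
Sedi-M,M,sediment,113°45.098′,22°27.206′,06/18/2011,12.0,–,–,7.60,200.4,67.7,2.3,0.62,0.52,0.50,0.38,0.69,0.42,–,–
Sedi-S,S,sediment,113°70.448′,21°95.165′,06/15/2011,20.0,–,–,7.40,5003.6,267.3,20.8,0.50,0.64,0.50,0.19,0.73,0.34,–,–
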
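number,channel,name,lam
1,ecg,RMSSD_R_amp,3
2,ecg,NN50_RR,5
3,ecg,SDSD_RR,3
4,ecg,tSD_RR,4
5,ecg,std_RR,4
6,ecg,mean,0
7,ecg,var,4
8,ecg,kurtosis,4
9,ecg,mean_RR,4
10,ecg,CV_EDR,2
11,ecg,mean_R_amp,1
12,ecg,var_EDR_D9,2
13,ecg,var_EDR_D2,0
14,ecg,entropy_D1,3
15,ecg,entropy_D2,3
16,ecg,entropy_D3,3
17,ecg,entropy_D4,3
18,ecg,entropy_D5,3
19,ecg,entropy_D6,2
20,ecg,entropy_D7,2
21,ecg,entropy_A7,0
22,ecg,mean_D1,0
23,ecg,mean_D2,0
24,ecg,mean_D3,0
25,ecg,mean_D4,0
26,ecg,mean_D5,0
27,ecg,mean_D6,1
28,ecg,mean_D7,0
29,ecg,mean_A7,0
30,ecg,var_D1,3
31,ecg,var_D2,4
32,ecg,var_D3,4
33,ecg,var_D4,3
34,ecg,var_D5,4
35,ecg,var_D6,3
36,ecg,var_D7,1
37,ecg,var_A7,0
38,ecg,WSD_RR,3
39,ecg,WSD_R_amp,4
40,ecg,max_PSD_0.03/0.5_,3
41,ecg,mean_PSD_10/20_,4
42,ecg,mean_PSD_80/100_,4
43,ecg,var_EDR_0.03/0.4_,1
44,ecg,var_RR_0.03/0.4_,1
45,ecg,spectral flatness,1
46,ecg,spectral centroid,0
47,ecg,spectral spread,5
48,ecg,spectral decrease,3
49,ecg,spectral slope,2
50,ecg,V_MAX,3
51,ecg,DET,4
52,ecg,LAM,3
53,ecg,SCrC_1_RR,0
54,ecg,SCrC_2_RR,2
55,ecg,SCrC_3_RR,2
56,ecg,SCrC_4_RR,4
57,ecg,SCrC_5_RR,1
58,ecg,std_PCA,1
59,ecg,std_kPCA,1
60,ecg,max_dia_PCA,4
61,ecg,max_dia_kPCA,4
62,ecg,RP_2_PC,2
63,spo2,med,4
64,spo2,RES4,5
65,spo2,mean_PSD_0.016/0.05_,4
66,spo2,SD_1_,5
67,airflow,mean,2
68,airflow,med,3
69,airflow,std,3
70,airflow,mean_PSD_0/0.1_,3
71,airflow,mean_PSD_0.4/0.5_,2
72,airflow,mean_D1,0
73,airflow,mean_D2,0
74,airflow,mean_D3,0
75,airflow,mean_A3,2
76,abdo,sum_abs,4
77,abdo,std_abs,5
78,abdo,mean,4
79,abdo,mean_PSD_80/100_,2
80,abdo,mean_D1,0
81,abdo,mean_D2,0
82,thor,sum,0
83,thor,std,3
84,thor,med,4
85,thor,mean,0
86,thor,var,3
87,thor,mean_PSD_80/100_,0
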
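roi_id,pipeline,ctr_smci_dm,ctr_smci_sd,ctr_pmci_dm,ctr_pmci_sd,ctr_pmci_flag,ctr_ad_dm,ctr_ad_sd,ctr_ad_flag,anova_p
3,CV,-0.10,0.36,-0.18,0.38,,-0.17,0.34,,
3,FS,-0.09,0.32,-0.21,0.35,,-0.19,0.33,,
4,CV,-0.12,0.27,-0.18,0.29,,-0.20,0.24,,
4,FS,-0.08,0.65,-0.20,0.68,,-0.19,0.57,,
5,CV,-0.10,0.41,-0.13,0.35,,-0.13,0.34,,
5,FS,-0.06,0.36,-0.13,0.37,,-0.13,0.37,,
6,CV,-0.08,0.32,-0.12,0.26,,-0.14,0.28,,
6,FS,-0.05,0.22,-0.15,0.23,,-0.16,0.23,,
33,CV,-0.10,0.41,-0.13,0.39,,-0.22,0.37,,
33,FS,-0.08,0.38,-0.13,0.35,,-0.15,0.38,,
18,CV,-0.09,0.47,-0.16,0.48,,-0.14,0.45,,
18,FS,-0.06,0.23,-0.21,0.20,pi,-0.17,0.22,omega,0.050
19,CV,-0.07,0.30,-0.14,0.29,,-0.19,0.28,,
19,FS,-0.05,0.32,-0.18,0.31,,-0.16,0.30,,
20,CV,-0.10,0.27,-0.17,0.26,,-0.23,0.27,,
20,FS,-0.08,0.33,-0.22,0.29,,-0.21,0.33,,
31,CV,-0.08,0.43,-0.18,0.37,,-0.18,0.38,,
31,FS,-0.10,0.41,-0.25,0.40,,-0.20,0.37,,
22,CV,-0.09,0.36,-0.18,0.35,,-0.18,0.41,,
22,FS,-0.06,0.35,-0.23,0.34,,-0.21,0.40,,
23,CV,-0.07,0.29,-0.15,0.32,,-0.19,0.25,,
23,FS,-0.05,0.30,-0.17,0.30,,-0.20,0.27,,
29,CV,-0.05,0.47,-0.11,0.44,,-0.11,0.45,,
29,FS,-0.06,0.48,-0.08,0.50,,-0.08,0.53,,
30,CV,-0.08,0.54,-0.21,0.55,,-0.22,0.51,,
30,FS,-0.10,0.65,-0.23,0.66,,-0.21,0.62,,
8,CV,-0.17,0.55,-0.18,0.55,,-0.38,0.67,,
8,FS,-0.14,0.73,-0.24,0.69,,-0.33,0.71,,
9,CV,-0.10,0.50,-0.10,0.51,,-0.23,0.59,,
9,FS,-0.07,0.99,-0.15,0.83,,-0.20,0.90,,
10,CV,-0.14,0.45,-0.15,0.38,,-0.24,0.44,,
10,FS,-0.12,0.62,-0.19,0.63,,-0.23,0.61,,
11,CV,-0.13,0.51,-0.16,0.51,,-0.31,0.48,,
11,FS,-0.12,0.74,-0.16,0.70,,-0.25,0.70,,
12,CV,-0.13,0.29,-0.18,0.23,,-0.33,0.25,,
12,FS,-0.11,0.61,-0.20,0.49,,-0.28,0.58,,
13,CV,-0.11,0.32,-0.20,0.35,,-0.27,0.33,,
13,FS,-0.08,0.54,-0.23,0.54,,-0.26,0.48,,
14,CV,-0.11,0.59,-0.14,0.62,,-0.30,0.56,,
14,FS,-0.11,0.81,-0.17,0.87,,-0.25,0.74,,
15,CV,-0.09,0.57,-0.15,0.59,,-0.29,0.66,,
15,FS,-0.11,0.41,-0.21,0.41,,-0.29,0.39,,
16,CV,-0.08,0.64,-0.13,0.57,,-0.21,0.58,,
16,FS,-0.09,0.62,-0.18,0.63,,-0.24,0.63,,
34,CV,-0.19,0.67,-0.28,0.67,,-0.55,0.63,,
34,FS,-0.21,1.21,-0.33,1.22,,-0.59,1.16,,
35,CV,-0.11,0.57,-0.15,0.59,,-0.32,0.56,,
35,FS,-0.10,1.25,-0.15,1.22,,-0.25,1.23,,
37,CV,-0.14,0.57,-0.17,0.59,,-0.35,0.52,,
37,FS,-0.15,0.80,-0.24,0.77,,-0.41,0.73,,
38,CV,-0.11,0.37,-0.11,0.38,,-0.30,0.35,,
38,FS,-0.13,0.46,-0.21,0.44,,-0.34,0.44,,
45,CV,-0.09,0.18,-0.12,0.18,,-0.22,0.18,,
45,FS,-0.11,0.24,-0.15,0.26,,-0.17,0.25,,
46,CV,-0.11,0.16,-0.13,0.14,,-0.21,0.14,omega,0.041
46,FS,-0.11,0.37,-0.17,0.38,,-0.20,0.37,,
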
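roi_id,pipeline,ctr_dm,ctr_sd,smci_dm,smci_sd,pmci_dm,pmci_sd,ad_dm,ad_sd,flag_ctr_pmci,flag_smci_pmci,flag_ctr_ad,flag_smci_ad,anova_p
3,CV,0.00,0.08,-0.04,0.12,-0.10,0.12,-0.13,0.12,0,0,1,1,0.0001
3,FS,-0.04,0.10,-0.06,0.13,-0.12,0.14,-0.13,0.12,0,0,1,0,0.0002
4,CV,-0.03,0.06,-0.05,0.10,-0.11,0.12,-0.13,0.12,1,0,1,1,0.0001
4,FS,-0.04,0.08,-0.06,0.13,-0.09,0.12,-0.11,0.13,0,0,1,0,0.0031
5,CV,-0.03,0.08,-0.03,0.11,-0.12,0.11,-0.15,0.13,1,1,1,1,0.0001
5,FS,-0.04,0.08,-0.05,0.15,-0.07,0.10,-0.09,0.11,0,0,0,0,
6,CV,-0.02,0.07,-0.04,0.10,-0.11,0.10,-0.14,0.12,1,0,1,1,0.0001
6,FS,-0.05,0.11,-0.05,0.15,-0.07,0.12,-0.11,0.11,0,0,0,0,
33,CV,-0.12,0.10,-0.03,0.15,-0.11,0.14,-0.15,0.16,1,0,1,1,0.0001
33,FS,-0.04,0.07,-0.05,0.11,-0.08,0.11,-0.10,0.09,0,0,1,0,0.0011
18,CV,-0.03,0.09,-0.02,0.10,-0.06,0.11,-0.09,0.10,0,0,1,1,0.0006
18,FS,-0.05,0.10,-0.05,0.14,-0.06,0.11,-0.08,0.10,0,0,0,0,
19,CV,-0.03,0.65,-0.04,0.09,-0.10,0.10,-0.12,0.11,1,0,1,1,0.0001
19,FS,-0.05,0.11,-0.04,0.10,-0.09,0.13,-0.12,0.12,0,0,1,0,0.0022
20,CV,-0.04,0.07,-0.05,0.10,-0.12,0.10,-0.14,0.11,1,0,1,1,0.0001
20,FS,-0.05,0.09,-0.05,0.12,-0.09,0.12,-0.12,0.11,0,0,1,1,0.0010
31,CV,-0.01,0.07,-0.02,0.07,-0.07,0.11,-0.11,0.11,0,0,1,1,0.0001
31,FS,-0.05,0.08,-0.03,0.07,-0.09,0.10,-0.11,0.10,0,0,1,1,0.0001
22,CV,-0.03,0.07,-0.02,0.09,-0.09,0.09,-0.11,0.11,0,1,1,1,0.0001
22,FS,-0.04,0.10,-0.06,0.13,-0.12,0.14,-0.13,0.12,0,0,1,0,0.0002
23,CV,-0.03,0.09,-0.03,0.11,-0.12,0.11,-0.15,0.15,1,0,1,1,0.0001
23,FS,-0.06,0.07,-0.05,0.10,-0.10,0.10,-0.07,0.09,0,0,0,0,
29,CV,0.00,0.08,0.01,0.13,-0.04,0.12,-0.11,0.14,0,0,1,1,0.0001
29,FS,-0.02,0.07,-0.04,0.11,-0.07,0.08,-0.08,0.09,0,0,1,0,0.0024
30,CV,-0.01,0.10,-0.02,0.07,-0.07,0.16,-0.12,0.12,0,0,1,1,0.0001
30,FS,-0.04,0.06,-0.04,0.07,-0.10,0.11,-0.11,0.09,1,0,1,1,0.0001
8,CV,-0.04,0.11,-0.05,0.19,-0.20,0.17,-0.27,0.29,1,0,1,1,0.0001
8,FS,-0.06,0.07,-0.09,0.11,-0.13,0.15,-0.18,0.14,0,0,1,0,0.0001
9,CV,-0.03,0.07,-0.04,0.11,-0.16,0.10,-0.16,0.11,1,1,1,1,0.0001
9,FS,-0.04,0.08,-0.06,0.10,-0.09,0.11,-0.12,0.10,0,0,1,0,0.0002
10,CV,-0.04,0.08,-0.05,0.11,-0.16,0.11,-0.16,0.11,1,1,1,1,0.0001
10,FS,-0.04,0.08,-0.06,0.14,-0.08,0.10,-0.10,0.11,0,0,0,0,
11,CV,-0.03,0.08,-0.06,0.13,-0.18,0.13,-0.21,0.15,1,1,1,1,0.0001
11,FS,-0.04,0.07,-0.07,0.14,-0.12,0.12,-0.10,0.10,1,0,1,0,0.0001
12,CV,-0.04,0.08,-0.06,0.12,-0.19,0.15,-0.20,0.12,1,1,1,1,0.0001
12,FS,-0.04,0.07,-0.06,0.12,-0.13,0.12,-0.14,0.11,1,0,1,1,0.0001
13,CV,-0.04,0.06,-0.04,0.10,-0.16,0.12,-0.16,0.11,1,1,1,1,0.0001
13,FS,-0.05,0.07,-0.06,0.12,-0.12,0.13,-0.11,0.10,0,0,1,0,0.0015
14,CV,-0.02,0.08,-0.07,0.13,-0.18,0.13,-0.21,0.20,1,0,1,1,0.0001
14,FS,-0.04,0.06,-0.08,0.12,-0.13,0.12,-0.14,0.11,1,0,1,0,0.0001
15,CV,-0.03,0.09,-0.07,0.13,-0.18,0.15,-0.19,0.18,1,1,1,1,0.0001
15,FS,-0.05,0.07,-0.08,0.10,-0.12,0.12,-0.14,0.11,1,0,1,1,0.0001
16,CV,-0.02,0.09,-0.03,0.10,-0.15,0.14,-0.16,0.15,1,1,1,1,0.0001
16,FS,-0.05,0.08,-0.06,0.09,-0.11,0.12,-0.12,0.09,0,0,1,0,0.0001
34,CV,-0.05,0.13,-0.12,0.15,-0.18,0.16,-0.27,0.27,0,0,1,1,0.0001
34,FS,-0.04,0.06,-0.08,0.08,-0.11,0.10,-0.14,0.10,1,0,1,1,0.0001
35,CV,-0.03,0.16,-0.07,0.09,-0.11,0.14,-0.17,0.21,0,0,1,1,0.0002
35,FS,-0.02,0.05,-0.04,0.07,-0.08,0.08,-0.07,0.08,1,0,1,0,0.0001
37,CV,-0.02,0.15,-0.06,0.15,-0.15,0.12,-0.24,0.30,0,0,1,1,0.0001
37,FS,-0.04,0.08,-0.07,0.09,-0.14,0.09,-0.17,0.13,1,0,1,1,0.0001
38,CV,-0.01,0.17,-0.03,0.11,-0.14,0.12,-0.20,0.26,0,0,1,1,0.0001
38,FS,-0.05,0.08,-0.07,0.12,-0.15,0.11,-0.17,0.12,1,0,1,0,0.0001
45,CV,-0.05,0.07,-0.06,0.11,-0.13,0.10,-0.15,0.12,1,0,1,1,0.0001
45,FS,-0.05,0.11,-0.06,0.16,-0.09,0.11,-0.08,0.12,0,0,0,0,
46,CV,-0.05,0.08,-0.05,0.11,-0.14,0.10,-0.15,0.12,1,1,1,1,0.0001
46,FS,-0.05,0.09,-0.04,0.12,-0.08,0.10,-0.08,0.11,1,0,1,0,
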
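group,n,age_mean,age_sd,education_mean,education_sd,male,female,mmse_bsl_mean,mmse_bsl_sd,delta_mmse_mean,delta_mmse_sd,apoe_nn_pct,apoe_nc_pct,apoe_cc_pct
CTR,69,75.6,4.8,15.9,2.9,38,31,29.2,1.0,0.1,1.4,66.5,28,5.5
sMCI,37,74.6,7.5,15.6,3.3,22,15,27.4,2.0,-0.4,1.8,35,60,5
pMCI,27,73.1,8,16.6,2.1,17,10,27.1,1.7,-3.4,3.6,40.5,44.5,15
AD,52,76.0,6.2,15.0,2.6,27,25,23.4,2.3,-3.9,5.1,31,50,19
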
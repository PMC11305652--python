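subject_id,group,sample_kind,albumin_g_dl,hemoglobin_g_dl,fco2,pco2_mmhg,ph,hco3_meq_l,so2,na,k,ca_mmol_l,mg_meq_l,cl,lac,acid_kind,acid_load_meq_l
diluted_mean,diluted,whole_blood,5.0,7.0,0.02,18.6,7.69,22.2,1.0,139.7,3.97,1.03,2.05,107,1.5,none,0
diluted_mean,diluted,whole_blood,5.0,7.0,0.12,66.9,7.25,29.6,1.0,141.6,3.98,1.28,2.07,104,1.4,none,0
diluted_mean,diluted,whole_blood,5.0,7.0,0.20,118.4,7.06,33.5,1.0,142.6,4.06,1.38,2.09,103,1.3,none,0
undiluted_mean,undiluted,whole_blood,5.0,14.1,0.02,19.9,7.60,19.6,1.0,139.2,4.10,1.09,2.02,110,1.9,none,0
undiluted_mean,undiluted,whole_blood,5.0,14.1,0.12,64.2,7.27,29.8,1.0,142.0,4.12,1.28,2.06,105,1.7,none,0
undiluted_mean,undiluted,whole_blood,5.0,14.1,0.20,121.2,7.08,36.1,1.0,143.8,4.22,1.37,2.10,103,1.6,none,0
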
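subject_id,group,sample_kind,albumin_g_dl,hemoglobin_g_dl,fco2,pco2_mmhg,ph,hco3_meq_l,so2,na,k,ca_mmol_l,mg_meq_l,cl,lac,acid_kind,acid_load_meq_l,beta_meq_ph
t3_mean,experiment3,whole_blood,5.0,13.9,0.0560,39.9,7.40,24.8,1.0,142.9,4.0,1.1,2.0,106.4,1.6,none,0,28.5
t3_mean,experiment3,whole_blood,5.0,13.9,0.0553,39.4,7.30,19.6,1.0,143.5,4.0,1.2,2.0,105.3,8.7,lactic,7.5,30.6
t3_mean,experiment3,whole_blood,5.0,13.9,0.0574,40.9,7.29,19.8,1.0,144.6,4.0,1.2,2.0,113.2,1.6,hcl,7.5,31.1
t3_mean,experiment3,whole_blood,5.0,13.9,0.0567,40.4,7.18,15.3,1.0,144.6,4.0,1.2,2.0,104.2,15.8,lactic,15,33.1
t3_mean,experiment3,whole_blood,5.0,13.9,0.0568,40.5,7.18,15.2,1.0,146.2,4.2,1.3,2.0,119.9,1.5,hcl,15,33.7
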
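subject_id,group,sample_kind,albumin_g_dl,hemoglobin_g_dl,fco2,pco2_mmhg,ph,hco3_meq_l,so2,na,k,ca_mmol_l,mg_meq_l,cl,lac,acid_kind,acid_load_meq_l
healthy_mean,healthy,whole_blood,4.8,14.2,0.02,18.2,7.61,18.0,1.0,137.3,4.23,1.09,2.10,111,1.9,none,0
healthy_mean,healthy,whole_blood,4.8,14.2,0.05,32.1,7.46,22.8,1.0,138.9,4.25,1.17,2.11,109,1.7,none,0
healthy_mean,healthy,whole_blood,4.8,14.2,0.12,68.3,7.24,29.6,1.0,140.7,4.32,1.28,2.11,106,1.7,none,0
healthy_mean,healthy,whole_blood,4.8,14.2,0.20,124.4,7.07,35.7,1.0,142.7,4.48,1.36,2.11,104,1.7,none,0
septic_mean,septic,whole_blood,3.1,10.4,0.02,18.3,7.56,16.8,1.0,138.7,4.35,1.05,2.00,112,3.8,none,0
septic_mean,septic,whole_blood,3.1,10.4,0.05,29.6,7.41,19.5,1.0,138.9,4.32,1.10,2.05,110,3.6,none,0
septic_mean,septic,whole_blood,3.1,10.4,0.12,67.2,7.17,25.1,1.0,140.4,4.48,1.17,2.05,108,3.6,none,0
septic_mean,septic,whole_blood,3.1,10.4,0.20,122.7,6.98,29.7,1.0,141.7,4.57,1.22,2.05,107,3.5,none,0
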
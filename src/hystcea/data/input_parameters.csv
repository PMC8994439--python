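id,base,low,high,family,units,source
route_share_post_tah,0.2058,,,point,probability,state discharge data
route_share_post_sah,0.0650,,,point,probability,state discharge data
route_share_post_vh,0.1529,,,point,probability,state discharge data
route_share_post_tlh,0.5150,,,point,probability,state discharge data
route_share_post_lsh,0.0612,,,point,probability,state discharge data
route_share_cf_tah,,,,derived,probability,complement of other counterfactual routes
route_share_cf_sah,0.0593,0.0581,0.0609,normal,probability,counterfactual standardization
route_share_cf_vh,0.1550,0.1532,0.1570,normal,probability,counterfactual standardization
route_share_cf_tlh,0.4646,0.4617,0.4671,normal,probability,counterfactual standardization
route_share_cf_lsh,0.1401,0.1379,0.1422,normal,probability,counterfactual standardization
morc_prop_post_tlh,0,,,point,probability,assumption
morc_prop_post_lsh,0,,,point,probability,assumption
morc_prop_cf_tlh,0.0765,0.0649,0.1680,beta,probability,literature
morc_prop_cf_lsh,0.75,0.60,1.00,beta,probability,literature
p_death_abdominal,0.0002,0,0.0007,beta,probability,literature and state discharge data
p_death_vaginal,,,,derived,probability,same as laparoscopic
p_death_laparoscopic,0.0001,0,0.0004,beta,probability,literature
p_major_tah,0.1462,0.1409,0.1516,normal,probability,state discharge data
p_major_sah,0.1316,0.1235,0.1397,normal,probability,state discharge data
p_major_vh,0.0538,0.0499,0.0577,normal,probability,state discharge data
p_major_tlh,0.0421,0.0404,0.0439,normal,probability,state discharge data
p_major_lsh,0.0317,0.0275,0.0360,normal,probability,state discharge data
p_minor_tah,0.0392,0.0364,0.0420,normal,probability,state discharge data
p_minor_sah,0.0328,0.0288,0.0369,normal,probability,state discharge data
p_minor_vh,0.0203,0.0179,0.0227,normal,probability,state discharge data
p_minor_tlh,0.0148,0.0138,0.0159,normal,probability,state discharge data
p_minor_lsh,0.0139,0.0112,0.0167,normal,probability,state discharge data
prev_endometrial_18_29,0.0010,0.0002,0.0029,normal,probability,literature
prev_endometrial_30_34,0.0011,0.0004,0.0018,normal,probability,literature
prev_endometrial_35_39,0.0012,0.0008,0.0017,normal,probability,literature
prev_endometrial_40_44,0.0016,0.0012,0.0019,normal,probability,literature
prev_endometrial_45_49,0.0028,0.0023,0.0032,normal,probability,literature
prev_endometrial_50_54,0.0069,0.0060,0.0078,normal,probability,literature
prev_endometrial_55_59,0.0166,0.0145,0.0187,normal,probability,literature
prev_endometrial_60_64,0.0247,0.0217,0.0276,normal,probability,literature
prev_endometrial_65_69,0.0272,0.0238,0.0306,normal,probability,literature
prev_endometrial_70_74,0.0288,0.0246,0.0330,normal,probability,literature
prev_endometrial_75plus,0.0393,0.0347,0.0438,normal,probability,literature
prev_sarcoma_18_29,0,,,point,probability,literature
prev_sarcoma_30_34,0.0005,0.0001,0.0012,normal,probability,literature
prev_sarcoma_35_39,0.0004,0.0002,0.0007,normal,probability,literature
prev_sarcoma_40_44,0.0011,0.0008,0.0013,normal,probability,literature
prev_sarcoma_45_49,0.0014,0.0011,0.0017,normal,probability,literature
prev_sarcoma_50_54,0.0035,0.0029,0.0041,normal,probability,literature
prev_sarcoma_55_59,0.0055,0.0043,0.0067,normal,probability,literature
prev_sarcoma_60_64,0.0053,0.0040,0.0067,normal,probability,literature
prev_sarcoma_65_69,0.0040,0.0026,0.0053,normal,probability,literature
prev_sarcoma_70_74,0.0026,0.0013,0.0039,normal,probability,literature
prev_sarcoma_75plus,0.0050,0.0034,0.0067,normal,probability,literature
weibull_endometrial_scale_morc,6.05,4.89,7.21,normal,log_months,registry linkage
weibull_endometrial_inc_supracervical,1.02,-0.27,2.32,normal,log_months,registry linkage
weibull_endometrial_inc_total,1.11,-0.07,2.29,normal,log_months,registry linkage
weibull_endometrial_shape,0.82,0.71,0.97,normal,shape,registry linkage
weibull_sarcoma_scale_morc,4.41,3.69,5.15,normal,log_months,registry linkage
weibull_sarcoma_inc_supracervical,0.78,-0.04,1.61,normal,log_months,registry linkage
weibull_sarcoma_inc_total,1.02,0.24,1.82,normal,log_months,registry linkage
weibull_sarcoma_shape,1.12,0.95,1.32,normal,shape,registry linkage
utility_laparoscopic,0.897,0.848,1,beta,utility,literature
utility_vaginal,,,,derived,utility,same as laparoscopic
utility_abdominal,0.892,0.72,1,beta,utility,literature
utility_perioperative_death,0,,,point,utility,assumption
utility_major_complication,0.48,0.38,0.835,beta,utility,literature
utility_minor_complication,0.61,0.43,0.917,beta,utility,literature
utility_endometrial_care,0.83,0.68,0.95,beta,utility,literature
utility_endometrial_eol_cancer,0.52,0.03,0.66,beta,utility,literature
utility_endometrial_eol_other,,,,derived,utility,same as initial/continuing phase
utility_sarcoma_care,0.67,0.30,0.91,beta,utility,literature
utility_sarcoma_eol_cancer,0.52,0.03,0.66,beta,utility,literature
utility_sarcoma_eol_other,,,,derived,utility,same as initial/continuing phase
cost_hysterectomy_tah,10282,10216,10348,lognormal,usd,state discharge data
cost_hysterectomy_sah,9556,9457,9657,lognormal,usd,state discharge data
cost_hysterectomy_vh,8275,8210,8341,lognormal,usd,state discharge data
cost_hysterectomy_tlh,11641,11595,11686,lognormal,usd,state discharge data
cost_hysterectomy_lsh,11099,10978,11222,lognormal,usd,state discharge data
cost_inc_death,18957,8273,37296,lognormal,usd,state discharge data
cost_inc_major,4205,4056,4360,lognormal,usd,state discharge data
cost_inc_minor,1471,1252,1675,lognormal,usd,state discharge data
cost_cancer_initial_lt65,3079,2801,3359,lognormal,usd_per_month,literature
cost_cancer_continuing_lt65,147,103,192,lognormal,usd_per_month,literature
cost_cancer_eol_cancer_lt65,10089,9723,10456,lognormal,usd_per_month,literature
cost_cancer_eol_other_lt65,425,59,792,lognormal,usd_per_month,literature
cost_cancer_initial_ge65,2566,2288,2846,lognormal,usd_per_month,literature
cost_cancer_continuing_ge65,147,103,192,lognormal,usd_per_month,literature
cost_cancer_eol_cancer_ge65,6726,6360,7093,lognormal,usd_per_month,literature
cost_cancer_eol_other_ge65,425,59,792,lognormal,usd_per_month,literature
weekly_earnings,726,364,1656,lognormal,usd_per_week,literature
recovery_weeks_abdominal,5,4,6,lognormal,weeks,literature
recovery_weeks_vaginal_laparoscopic,3,2,4,lognormal,weeks,literature
prodloss_initial,203,192,214,lognormal,usd_per_month,literature
prodloss_continuing,83,72,94,lognormal,usd_per_month,literature
prodloss_eol_cancer,240,222,260,lognormal,usd_per_month,literature
prodloss_eol_other,,,,derived,usd_per_month,same as continuing phase
discount_rate_annual,0.03,,,point,fraction,convention
national_share,0.2989,,,point,fraction,population coverage of study states
psa_iterations,1000,,,point,count,analysis setting
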
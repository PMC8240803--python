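category,concept_id,keyword,df_2011,df_2012,df_2013,df_2014,df_2015,avg_growth_printed,avg_df_printed
socioeconomic_cultural,population_aging,Population aging,7463,8912,8002,4499,4503,0.088,6676
socioeconomic_cultural,economic_problems,Economic problems,1637,2054,2523,1471,1503,0.214,1838
socioeconomic_cultural,nuclearization_of_the_family,Nuclearization of the family,1178,1288,1229,667,628,0.054,998
socioeconomic_cultural,changing_perspectives_about_marriage,Changing perspectives about marriage,1046,1528,1116,596,484,0.034,954
socioeconomic_cultural,conservative_values,Conservative values,1150,1195,1139,576,565,0.036,925
socioeconomic_cultural,violence_and_abuse,Violence and abuse,685,800,726,461,527,0.158,640
socioeconomic_cultural,employment_problems,Employment problems,515,510,436,306,208,-0.008,395
socioeconomic_cultural,gender_inequality,Gender inequality,286,298,319,190,133,0.027,245
fertility_policy,financial_support_for_childbirth,Financial support for childbirth,3061,3145,2548,1573,1250,-0.015,2315
fertility_policy,child_safety_protection_system,Child-safety protection system,1757,1632,1974,1241,1292,0.156,1579
fertility_policy,infrastructure_for_childcare_support,Infrastructure for childcare support,1853,2209,1310,829,579,-0.061,1356
fertility_policy,maternity_leave_system,Maternity-leave system,1067,995,798,828,383,0.044,814
fertility_policy,policy_public_relations,Policy public relations,878,883,894,648,361,0.015,733
fertility_policy,financial_support_for_employment_security,Financial support for employment security,392,341,345,233,196,0.045,301
fertility_policy,flexible_working_arrangement,Flexible working arrangement,330,264,354,287,180,0.120,283
fertility_policy,family_friendly_work_environment,Family-friendly work environment,161,130,77,49,35,-0.146,90
fertility_policy,smart_work_center,Smart work center,131,114,90,50,27,-0.161,82
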
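surface_form,concept_id,concept_kind
childbirth celebration money,financial_support_for_childbirth,class
childbirth grant,financial_support_for_childbirth,class
subsidy,financial_support_for_childbirth,class
baby bonus,financial_support_for_childbirth,class
childbirth incentive,financial_support_for_childbirth,class
aging society,population_aging,class
ageing population,population_aging,class
economic burden,economic_problems,class
economic hardship,economic_problems,class
nuclear family,nuclearization_of_the_family,class
nuclear families,nuclearization_of_the_family,class
views on marriage,changing_perspectives_about_marriage,class
marriage values shift,changing_perspectives_about_marriage,class
traditional values,conservative_values,class
patriarchal values,conservative_values,class
child abuse,violence_and_abuse,class
domestic violence,violence_and_abuse,class
school violence,violence_and_abuse,class
job insecurity,employment_problems,class
unemployment,employment_problems,class
gender discrimination,gender_inequality,class
glass ceiling,gender_inequality,class
child protection,child_safety_protection_system,class
child safety policy,child_safety_protection_system,class
daycare center expansion,infrastructure_for_childcare_support,class
childcare facilities,infrastructure_for_childcare_support,class
maternity leave,maternity_leave_system,class
parental leave pay,maternity_leave_system,class
policy campaign,policy_public_relations,class
government pr,policy_public_relations,class
employment subsidy,financial_support_for_employment_security,class
job security support,financial_support_for_employment_security,class
flexible hours,flexible_working_arrangement,class
flexitime,flexible_working_arrangement,class
telecommuting,flexible_working_arrangement,class
family friendly workplace,family_friendly_work_environment,class
smart work centre,smart_work_center,class
birth control,contraceptive_use,class
birth control method,hasType,attribute
length of contraceptive use,hasLengthOfUse,attribute
the pill,pill,value
iud,intrauterine device,value
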
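class_id,label,parent_ids,level
determinants_of_fertility,Determinants of fertility,,0
individual,Individual,determinants_of_fertility,1
family,Family,determinants_of_fertility,1
workplace,Workplace,determinants_of_fertility,1
childcare_educational_environment,Childcare and educational environment,determinants_of_fertility,1
socioeconomic_cultural_environment,Socioeconomic and cultural environment,determinants_of_fertility,1
public_policy,Public policy,determinants_of_fertility,1
womens_sociodemographic_data,Women's sociodemographic data,individual,2
age,Age,womens_sociodemographic_data,3
education,Education,womens_sociodemographic_data,3
employment,Employment,womens_sociodemographic_data,3
religion,Religion,womens_sociodemographic_data,3
reproductive_health,Reproductive health,individual,2
sexual_behavior,Sexual behavior,reproductive_health,3
contraceptive_use,Contraceptive use,reproductive_health,3
childbirth,Childbirth,reproductive_health,3
individuals_attitude,Individual's attitude,individual,2
attitude_toward_children,Attitude toward children,individuals_attitude,3
attitude_toward_marriage,Attitude toward marriage,individuals_attitude,3
familys_sociodemographic_data,Family's sociodemographic data,family,2
family_size,Family size,familys_sociodemographic_data,3
family_income,Family income,familys_sociodemographic_data,3
family_expenditure,Family expenditure,familys_sociodemographic_data,3
sex_and_age_of_children,Sex and age of children,familys_sociodemographic_data,3
number_of_children,Number of children,familys_sociodemographic_data,3
spouses_age,Spouse's age,familys_sociodemographic_data,3
spouses_income,Spouse's income,familys_sociodemographic_data,3
family_members_relationship,Family member's relationship,family,2
gender_equality,Gender equality,family_members_relationship,3
couples_intimacy,Couple's intimacy,family_members_relationship,3
familys_life_satisfaction,Family's life satisfaction,family_members_relationship,3
family_formation_factors,Family-formation factors,family,2
marriage_cost,Marriage cost,family_formation_factors,3
workplace_structure,Workplace structure,workplace,2
workplace_type,Workplace type,workplace_structure,3
working_hours,Working hours,workplace_structure,3
employment_insurance,Employment insurance,workplace_structure,3
workplace_culture,Workplace culture,workplace,2
parental_leave_availability,Parental leave availability,workplace_culture,3
childcare_educational_structure,Childcare and educational structure,childcare_educational_environment,2
childcare_type,Childcare type,childcare_educational_structure,3
childcare_cost,Childcare cost,childcare_educational_structure,3
childcare_service,Childcare service,childcare_educational_structure,3
childcare_human_resources,Childcare human resources,childcare_educational_structure,3
childcare_environment_satisfaction,Childcare and educational environment satisfaction,childcare_educational_environment,2
belief_of_quality,Belief of the quality,childcare_environment_satisfaction,3
sociocultural_environment,Sociocultural environment,socioeconomic_cultural_environment,2
social_value,Social value,sociocultural_environment,3
mass_media,Mass media,sociocultural_environment,3
social_change,Social change,sociocultural_environment,3
economic_environment,Economic environment,socioeconomic_cultural_environment,2
economic_growth,Economic growth,economic_environment,3
population_aging,Population aging,social_change,4
nuclearization_of_the_family,Nuclearization of the family,social_change,4
violence_and_abuse,Violence and abuse,social_change,4
changing_perspectives_about_marriage,Changing perspectives about marriage,social_value,4
conservative_values,Conservative values,social_value,4
gender_inequality,Gender inequality,social_value,4
economic_problems,Economic problems,economic_environment,3
employment_problems,Employment problems,economic_environment,3
policy_on_low_fertility,Policy on low fertility,public_policy,2
policy_area,Policy area,policy_on_low_fertility,3
legal_basis,Legal basis,policy_on_low_fertility,3
policy_tasks,Policy tasks,policy_on_low_fertility,3
financial_support_for_childbirth,Financial support for childbirth,policy_area,4
child_safety_protection_system,Child-safety protection system,policy_area,4
infrastructure_for_childcare_support,Infrastructure for childcare support,policy_area,4
maternity_leave_system,Maternity-leave system,policy_area,4
policy_public_relations,Policy public relations,policy_area,4
financial_support_for_employment_security,Financial support for employment security,policy_area,4
flexible_working_arrangement,Flexible working arrangement,policy_area,4
family_friendly_work_environment,Family-friendly work environment,policy_area,4
smart_work_center,Smart work center,policy_area,4
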
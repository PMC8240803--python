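concept_id,signal
violence_and_abuse,weak
flexible_working_arrangement,weak
financial_support_for_employment_security,weak
economic_problems,strong
nuclearization_of_the_family,strong
population_aging,strong
child_safety_protection_system,strong
maternity_leave_system,strong
gender_inequality,latent
employment_problems,latent
changing_perspectives_about_marriage,latent
policy_public_relations,latent
family_friendly_work_environment,latent
smart_work_center,latent
conservative_values,not_strong_but_well_known
financial_support_for_childbirth,not_strong_but_well_known
infrastructure_for_childcare_support,not_strong_but_well_known
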
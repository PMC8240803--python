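relation_name,domain_id,range_id
hasIndividual,determinants_of_fertility,individual
isIndividualOf,individual,determinants_of_fertility
hasFamily,determinants_of_fertility,family
isFamilyOf,family,determinants_of_fertility
hasWorkplace,determinants_of_fertility,workplace
isWorkplaceOf,workplace,determinants_of_fertility
hasChildcareEducationalEnvironment,determinants_of_fertility,childcare_educational_environment
isChildcareEducationalEnvironmentOf,childcare_educational_environment,determinants_of_fertility
hasSocioeconomicCulturalEnvironment,determinants_of_fertility,socioeconomic_cultural_environment
isSocioeconomicCulturalEnvironmentOf,socioeconomic_cultural_environment,determinants_of_fertility
hasPublicPolicy,determinants_of_fertility,public_policy
isPublicPolicyOf,public_policy,determinants_of_fertility
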
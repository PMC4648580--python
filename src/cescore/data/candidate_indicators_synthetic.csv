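name,field,n_articles,n_indexes,update_frequency,in_over_third_of_caps,in_worldbank
gni_per_capita,economics,,,,,
u5mr,health,,,,,
adult_literacy,education,,,,,
underweight,nutrition,,,,,
affected_persons,displacement,,,,,
uprooted_persons,displacement,,,,,
crude_mortality_rate,health,,,,,
excess_mortality,health,,,,,
infant_mortality,health,,,,,
maternal_mortality,health,,,,,
life_expectancy,health,,,,,
measles_immunization,health,,,,,
physicians_per_capita,health,,,,,
global_acute_malnutrition,nutrition,,,,,
stunting,nutrition,,,,,
food_insecure_population,nutrition,,,,,
access_to_improved_water,water_sanitation,,,,,
access_to_sanitation,water_sanitation,,,,,
poverty_headcount,economics,,,,,
gdp_per_capita,economics,,,,,
primary_school_enrolment,education,,,,,
human_development_index,composite,,,,,
internally_displaced_persons,displacement,,,,,
refugees,displacement,,,,,
conflict_related_deaths,security,,,,,
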
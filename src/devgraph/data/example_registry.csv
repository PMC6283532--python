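id,name,life_stage,polarity,ceiling,units
total_population,Total population,socioeconomic,neutral,false,persons
gni_per_capita,GNI per capita,socioeconomic,higher_desirable,false,US$
preprimary_enrollment_m,Preprimary school participation (male),socioeconomic,higher_desirable,false,%
preprimary_enrollment_f,Preprimary school participation (female),socioeconomic,higher_desirable,false,%
primary_enrollment,Primary school participation,socioeconomic,higher_desirable,true,%
primary_survival_last_grade,Survival rate to last primary grade,socioeconomic,higher_desirable,false,%
secondary_enrollment,Secondary school participation,socioeconomic,higher_desirable,false,%
adult_literacy,Total adult literacy rate,socioeconomic,higher_desirable,true,%
life_expectancy,Life expectancy at birth,socioeconomic,higher_desirable,false,years
maternal_mortality,Adjusted maternal mortality rate,gestation_birth,lower_desirable,false,per 100000 live births
low_birthweight,Low birthweight,gestation_birth,lower_desirable,false,%
neonatal_mortality,Neonatal mortality rate,gestation_birth,lower_desirable,false,per 1000 live births
infant_mortality,Infant mortality rate (<12 months),infancy_under5,lower_desirable,false,per 1000 live births
exclusive_breastfeeding,Exclusive breastfeeding <6 months,infancy_under5,higher_desirable,false,%
solid_food_6_8mo,Introduction of solid food 6-8 months,infancy_under5,higher_desirable,false,%
iodized_salt,Adequate iodized salt consumption,infancy_under5,higher_desirable,false,%
vitamin_a_supplementation,Vitamin A supplementation full coverage,infancy_under5,higher_desirable,true,%
underweight_u5,Underweight prevalence <5 years,infancy_under5,lower_desirable,false,%
stunting_u5,Stunting prevalence <5 years,infancy_under5,lower_desirable,false,%
wasting_u5,Wasting prevalence <5 years,infancy_under5,lower_desirable,false,%
overweight_u5,Overweight prevalence <5 years,infancy_under5,lower_desirable,false,%
under5_mortality,Mortality rate <5 years,infancy_under5,lower_desirable,false,per 1000 live births
diarrhea_deaths_u5,Diarrhea deaths from inadequate WASH <5 years,wash,lower_desirable,false,per 100000
basic_water_urban,Basic drinking-water services (urban),wash,higher_desirable,false,%
basic_water_rural,Basic drinking-water services (rural),wash,higher_desirable,false,%
basic_water_national,Basic drinking-water services (national),wash,higher_desirable,false,%
basic_sanitation_urban,Basic sanitation services (urban),wash,higher_desirable,false,%
basic_sanitation_rural,Basic sanitation services (rural),wash,higher_desirable,false,%
basic_sanitation_national,Basic sanitation services (national),wash,higher_desirable,false,%
insufficient_activity_m,Insufficient physical activity (men),adult_lifestyle,lower_desirable,false,%
insufficient_activity_f,Insufficient physical activity (women),adult_lifestyle,lower_desirable,false,%
alcohol_per_capita,Alcohol consumption per capita,adult_lifestyle,lower_desirable,false,L pure alcohol
alcohol_use_disorders_m,Alcohol-use disorders 12-month prevalence (men),adult_lifestyle,lower_desirable,false,%
alcohol_use_disorders_f,Alcohol-use disorders 12-month prevalence (women),adult_lifestyle,lower_desirable,false,%
tobacco_smoking_m,Current tobacco smoking (men),adult_lifestyle,lower_desirable,false,%
tobacco_smoking_f,Current tobacco smoking (women),adult_lifestyle,lower_desirable,false,%
mean_bmi_m,Mean body mass index (men),adult_biomarker,lower_desirable,false,kg/m2
mean_bmi_f,Mean body mass index (women),adult_biomarker,lower_desirable,false,kg/m2
overweight_adult_m,Overweight BMI>=25 (men),adult_biomarker,lower_desirable,false,%
overweight_adult_f,Overweight BMI>=25 (women),adult_biomarker,lower_desirable,false,%
obesity_m,Obesity BMI>=30 (men),adult_biomarker,lower_desirable,false,%
obesity_f,Obesity BMI>=30 (women),adult_biomarker,lower_desirable,false,%
raised_bp_m,Raised blood pressure (men),adult_biomarker,lower_desirable,false,%
raised_bp_f,Raised blood pressure (women),adult_biomarker,lower_desirable,false,%
raised_glucose_m,Raised blood glucose (men),adult_biomarker,lower_desirable,false,%
raised_glucose_f,Raised blood glucose (women),adult_biomarker,lower_desirable,false,%
diabetes_mortality_m,Diabetes mortality (men),ncd_mortality,lower_desirable,false,per 100000
diabetes_mortality_f,Diabetes mortality (women),ncd_mortality,lower_desirable,false,per 100000
cvd_mortality_m,Cardiovascular disease mortality (men),ncd_mortality,lower_desirable,false,per 100000
cvd_mortality_f,Cardiovascular disease mortality (women),ncd_mortality,lower_desirable,false,per 100000
resp_mortality,Chronic respiratory disease mortality,ncd_mortality,lower_desirable,false,per 100000
cancer_mortality_m,Cancer mortality (men),ncd_mortality,lower_desirable,false,per 100000
cancer_mortality_f,Cancer mortality (women),ncd_mortality,lower_desirable,false,per 100000
ncd_mortality_other,Other NCD mortality,ncd_mortality,lower_desirable,false,per 100000
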
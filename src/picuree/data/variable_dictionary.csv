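variable,units,type,description
id,,integer,Record identifier
male,,indicator,Male sex (male + female = 1)
female,,indicator,Female sex
caucasian,,indicator,Ethnic origin: Caucasian (the four indicators sum to 1)
asian,,indicator,Ethnic origin: Asian
south_american,,indicator,Ethnic origin: South American
african,,indicator,Ethnic origin: African
mechanically_ventilated,,indicator,Mechanical ventilation at measurement
age,years,continuous,Age
weight,kg,continuous,Body weight
height,cm,continuous,Length or standing height
bmi,kg/m^2,continuous,Body mass index
z_bmi,,continuous,BMI-for-age z-score
z_hfa,,continuous,Height-for-age z-score
z_wfa,,continuous,Weight-for-age z-score (missing above 10 y)
z_wfh,,continuous,Weight-for-length/height z-score (missing above 5 y)
normal_weight,,indicator,Weight class: normal (exactly one of normal/overweight/obese)
overweight,,indicator,Weight class: overweight
obese,,indicator,Weight class: obese
stunting,,indicator,Height-for-age z < -2
wasting_none,,indicator,No wasting (the four wasting indicators sum to 1)
wasting_mild,,indicator,Mild wasting (age-appropriate z < -1)
wasting_moderate,,indicator,Moderate wasting (z < -2)
wasting_severe,,indicator,Severe wasting (z < -3)
vo2,L/min,continuous,Oxygen consumption
vco2,L/min,continuous,Carbon dioxide production
rq,,continuous,Respiratory quotient (vco2/vo2)
heart_rate,bpm,continuous,Heart rate
sbp,mmHg,continuous,Systolic blood pressure
dbp,mmHg,continuous,Diastolic blood pressure
sat_o2,%,continuous,Oxygen saturation
body_temperature,degC,continuous,Body temperature
crp,mg/dL,continuous,C-reactive protein
hemoglobin,g/dL,continuous,Hemoglobin
blood_glucose,mg/dL,continuous,Blood glucose
measured_ree,kcal/day,continuous,Measured resting energy expenditure (target)
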
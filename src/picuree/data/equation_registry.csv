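id,sex,age_lo_years,age_hi_years,intercept,coef_weight,coef_height,coef_age,citation
harris_benedict,male,0,100,66.473,13.7516,5.0033,-6.755,"Harris JA, Benedict FG. PNAS 1918;4:370-373"
harris_benedict,female,0,100,655.0955,9.5634,1.8496,-4.6756,"Harris JA, Benedict FG. PNAS 1918;4:370-373"
harris_benedict_infants,male,0,1,22.10,31.05,1.16,0,"Harris JA, Benedict FG. Biometric studies of basal metabolism in man, 1919 (infant series)"
harris_benedict_infants,female,0,1,22.10,31.05,1.16,0,"Harris JA, Benedict FG. Biometric studies of basal metabolism in man, 1919 (infant series)"
schofield_w,male,0,3,-30.4,59.512,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_w,male,3,10,504.3,22.706,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_w,male,10,18,658.2,17.686,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_w,female,0,3,-31.1,58.317,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_w,female,3,10,485.9,20.315,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_w,female,10,18,692.6,13.384,0,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41"
schofield_wh,male,0,3,-617.6,0.167,15.174,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
schofield_wh,male,3,10,414.9,19.59,1.303,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
schofield_wh,male,10,18,515.5,16.25,1.372,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
schofield_wh,female,0,3,-413.5,16.252,10.232,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
schofield_wh,female,3,10,371.2,16.969,1.618,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
schofield_wh,female,10,18,200.0,8.365,4.65,0,"Schofield WN. Hum Nutr Clin Nutr 1985;39 Suppl 1:5-41 (height converted m->cm)"
oxford_w,male,0,3,-33.7,61.0,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_w,male,3,10,514,23.3,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_w,male,10,18,581,18.4,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_w,female,0,3,-23.1,58.9,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_w,female,3,10,507,20.1,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_w,female,10,18,761,11.1,0,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152"
oxford_wh,male,0,3,-371,28.2,8.59,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
oxford_wh,male,3,10,306,15.1,0.742,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
oxford_wh,male,10,18,299,15.6,2.66,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
oxford_wh,female,0,3,-287,30.4,7.03,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
oxford_wh,female,3,10,349,15.9,2.10,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
oxford_wh,female,10,18,462,9.40,2.49,0,"Henry CJ. Public Health Nutr 2005;8:1133-1152 (height converted m->cm)"
fao_who_unu,male,0,3,-54,60.9,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
fao_who_unu,male,3,10,495,22.7,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
fao_who_unu,male,10,18,651,17.5,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
fao_who_unu,female,0,3,-51,61.0,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
fao_who_unu,female,3,10,499,22.5,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
fao_who_unu,female,10,18,746,12.2,0,0,"FAO/WHO/UNU. Energy and protein requirements. WHO TRS 724, 1985"
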
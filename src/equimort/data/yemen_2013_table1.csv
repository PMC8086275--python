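indicator,dimension,subgroup,estimate,ci_low,ci_high,population,national
imr,wealth_quintile,1,53.23,46.06,61.44,7313,0
imr,wealth_quintile,2,58.26,50.18,67.53,6873,0
imr,wealth_quintile,3,46.91,40.65,54.07,6356,0
imr,wealth_quintile,4,37.45,31.71,44.17,5886,0
imr,wealth_quintile,5,33.03,26.44,41.20,5314,0
imr,education,none,49.74,45.23,54.67,19075,0
imr,education,primary,45,39.63,51.05,9291,0
imr,education,secondary+,34.15,26.46,43.97,3377,0
imr,residence,rural,50.79,46.50,55.45,23210,0
imr,residence,urban,35.71,30.67,41.56,8533,0
imr,sex,female,45.02,40.7,49.78,15519,0
imr,sex,male,48.37,43.99,53.15,16224,0
imr,region,Ibb,51.50,35.99,73.18,3480,0
imr,region,Abyan,41.02,28.27,59.16,572,0
imr,region,Sanaa City,31.56,24.07,41.29,2586,0
imr,region,Al-Baidha,61.40,53.56,70.31,1253,0
imr,region,Taiz,50.88,39.79,64.85,3919,0
imr,region,Al-Jawf,26.07,12.71,52.72,277,0
imr,region,Hajjah,32.24,23.15,44.73,2152,0
imr,region,Al-Hodiedah,49.11,38.98,61.71,4037,0
imr,region,Hadramout,26.76,18.98,37.62,1566,0
imr,region,Dhamar,60.93,49.66,74.55,2644,0
imr,region,Shabwah,29.77,19.71,44.72,562,0
imr,region,Sadah,43.16,31.05,59.72,1046,0
imr,region,Sanaa,59.77,47.68,74.68,1720,0
imr,region,Aden,35.31,22.67,54.60,776,0
imr,region,Lahj,27.98,18.49,42.13,777,0
imr,region,Mareb,,,,237,0
imr,region,Al-Mhweit,54.97,45.03,66.94,1005,0
imr,region,Al-Mhrah,,,,121,0
imr,region,Amran,58.51,46.16,73.92,1353,0
imr,region,Aldhalae,42.61,34.89,51.94,804,0
imr,region,Reimah,53.42,43.22,65.87,847,0
imr,all,national_average,46.73,,,31743,1
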
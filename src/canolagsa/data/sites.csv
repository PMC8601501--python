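site,province,latitude,longitude,altitude_m,mean_temp_C,rain_mm,radiation_MJ_m2,years,planting_date,row_spacing_cm,population_per_m2,n_rate_kg_ha
Luxi,Yunnan,24.32,103.46,1704.3,15.0,240.2,2954.3,2018,09-20,25,45,174
Chongqing,Chongqing,29.35,106.28,259.1,14.4,411.7,1718.4,2018,09-28,25,45,174
Hanzhong,Shanxi,33.04,107.02,509.5,10.4,221.2,1976.7,2018,09-26,25,45,174
Zhuzhou,Hunan,27.52,113.10,74.6,12.5,958.7,1791.6,2018,09-28,25,45,174
Wuhu,Anhui,31.09,118.35,17.1,11.1,572.8,2090.2,2018,10-01,25,45,174
Gaoyou,Jiangsu,32.48,119.27,5.4,10.5,354.8,2365.0,2018,10-03,25,45,174
Hangzhou,Zhejiang,30.14,120.10,41.7,12.4,839.9,2040.5,2018,10-05,25,45,174
Wuhan,Hubei,30.47,114.35,23.6,17.4,530.6,2162.4,2011-2018,09-28,25,45,174
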
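dataset,role,sowing_date,n_rate_kg_ha,population_per_m2,anthesis_date,maturity_date,yield_kg_ha,biomass_kg_ha
1,calibration,2014-09-25,240,45,2015-02-22,2015-04-28,2648,13293
2,calibration,2015-09-24,199,45,2016-02-20,2016-04-22,2676,9757
3,evaluation,2016-09-27,199,45,2017-02-14,2017-04-25,2641,9394
4,evaluation,2017-09-25,139,45,2018-03-02,2018-04-30,2929,12467
5,evaluation,2018-09-27,139,45,2019-03-04,2019-05-01,2765,12328
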
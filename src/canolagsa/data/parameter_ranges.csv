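name,definition,lower,upper,group
PL-EM,Time between planting and emergence (thermal days),2.52,4.68,ecotype
EM-V1,Time required from emergence to first true leaf (thermal days),4.2,7.8,ecotype
JU-R0,Time required for floral induction under optimal temperature and daylength (thermal days),3.5,6.5,ecotype
PM09,Proportion of time between first seed and physiological maturity that the last seed can be formed,0.25,0.46,ecotype
LNGSH,Time required for growth of individual shells (thermal days),7,13,ecotype
R7-R8,Time between physiological and harvest maturity (thermal days),8.4,15.6,ecotype
TRIFL,Rate of appearance of leaves on the mainstem,0.22,0.42,ecotype
RWDTH,Relative canopy width versus the standard width per node,0.7,1.3,ecotype
RHGHT,Relative canopy height versus the standard height per node,0.63,1.17,ecotype
R1PPO,Increase in daylength sensitivity after flower appearance (h),0.35,0.66,ecotype
OPTBI,Minimum daily temperature above which development toward flowering is not slowed (degC),14,26,ecotype
SLOBI,Slope reducing progress toward flowering when TMIN is below OPTBI,0.02,0.05,ecotype
CSDL,Critical short daylength below which reproductive development is daylength-limited (h),14,24,genotype
EM-FL,Time between plant emergence and flower appearance (photothermal days),20,45,genotype
FL-SH,Time between first flower and first pod (photothermal days),10,16,genotype
FL-SD,Time between first flower and first seed (photothermal days),15,35,genotype
SD-PM,Time between first seed and physiological maturity (photothermal days),20,40,genotype
FL-LF,Time between first flower and end of leaf expansion (photothermal days),1,10,genotype
SLAVR,Specific leaf area under standard growth conditions (cm2/g),200,275,genotype
SIZLF,Maximum size of full leaf (cm2),90,110,genotype
SFDUR,Seed filling duration per pod cohort (photothermal days),18,22,genotype
SDPDV,Average seeds per pod under standard growing conditions,15,25,genotype
PODUR,Time to reach final pod load under optimal conditions (photothermal days),8,12,genotype
SLLL,Soil water lower limit (cm3/cm3),0.055,0.123,soil
SDUL,Soil water drained upper limit (cm3/cm3),0.123,0.348,soil
SSAT,Soil water saturated upper limit (cm3/cm3),0.348,0.547,soil
SRGF,Root growth factor,0.7,1.0,soil
SSKS,Saturated hydraulic conductivity (cm/h),0.06,21.0,soil
SBDM,Bulk density (g/cm3),1.0,1.4,soil
SLOC,Organic carbon content (%),0.348,5.0,soil
SALB,Soil albedo,0.09,0.17,soil
SLU1,Stage-one evaporation limit (mm),2,12,soil
SLDR,Drainage rate (fraction/day),0.01,0.85,soil
SLRO,Runoff curve number,61,94,soil
SLNF,Mineralization factor,0,1,soil
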
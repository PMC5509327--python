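study_id,ethnicity,snp_ids,risk_alleles,rafs,n,beta,beta_se,beta_ci_low,beta_ci_high,beta_p,hom_risk_n,hom_risk_mean,hom_risk_sd,het_n,het_mean,het_sd,hom_other_n,hom_other_mean,hom_other_sd,hwe_ok
NewHoorn-2009,Caucasian,rs560887,G,0.693,2225,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
CoLaus-2009,Caucasian,rs560887,G,0.72,5000,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Framingham-2009,Caucasian,rs560887,G,0.70,6479,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Rotterdam-2009,Caucasian,rs560887,G,0.69,2058,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Sardinia-2009,Caucasian,rs560887,G,0.63,4305,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Japanese-2009,Asian,rs560887,G,0.97,4813,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
SriLankan-2009,Asian,rs560887,G,0.91,2319,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,no
IndianAsian-2009,Asian,rs560887,G,0.85,5089,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
EuropeanWhites-2009,Caucasian,rs560887,G,0.69,4462,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Haguenau-2010,Caucasian,rs560887;rs573225,G;A,NA;NA,1201,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
DESIR-2010,Caucasian,rs560887;rs573225,G;A,NA;NA,3483,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
NFBC86-2010,Caucasian,rs560887;rs573225,G;A,NA;NA,4372,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ObeseChildren-2010,Caucasian,rs560887;rs573225,G;A,NA;NA,476,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
HUFS-2010,African-American,rs560887,G,0.957,927,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
GLACIER-2010,Caucasian,rs560887,G,0.71,1630,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
MAGIC-2010,Caucasian,rs560887,G,0.70,76558,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
FrenchControls-2011,Caucasian,rs560887,G,0.70,634,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
EYHS-2011,Caucasian,rs560887,G,0.70,1934,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
FrenchCases-2011,Caucasian,rs560887,G,0.70,581,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Raine-2011,Caucasian,rs560887,G,0.70,1045,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ALSPAC-2011,Caucasian,rs560887,G,0.70,1736,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
SouthAsians-2011,Asian,rs560887,G,0.84,1163,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
CAU-2012,Caucasian,rs560887,G,0.72,2349,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
CHN-2012,Asian,rs560887,G,0.97,664,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
AFA-2012,African-American,rs560887,G,0.93,1366,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,no
HIS-2012,Caucasian,rs560887,G,0.86,1171,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
DESIRcohort-2013,Caucasian,rs560887;rs573225,G;A,0.695;0.670,4220,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ZhengCaucasians-2015,Caucasian,rs560887,G,0.723,336,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ZhengHispanics-2015,Caucasian,rs560887,G,0.834,205,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ZhengAfricanAmericans-2015,African-American,rs560887,G,0.934,211,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
1000G-2015,Caucasian,rs560887,G,0.69,40091,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
MexicanChildren-2016,mixed,rs560887,G,0.913,1421,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
HealthyAdults-2010,Asian,rs16856187,A,0.303,583,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
HealthyAdolescents-2010,Asian,rs16856187,A,0.299,1061,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Shanghai-2008,Asian,rs16856187,A,0.303,1800,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
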
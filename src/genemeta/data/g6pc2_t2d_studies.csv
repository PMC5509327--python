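study_id,ethnicity,snp_id,risk_allele,n_case,n_control,raf_case,raf_control,case_hom_risk,case_het,case_hom_other,control_hom_risk,control_het,control_hom_other,reported_or,reported_ci_low,reported_ci_high,hwe_ok
European-2008,Caucasian,rs560887,G,2792,4073,NA,0.70,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
NewHoorn-2009,Caucasian,rs560887,G,2628,2041,NA,0.692,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Inter99-2009,Caucasian,rs560887,G,1963,4913,NA,0.689,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Japanese-2009,Asian,rs560887,G,5629,6406,NA,0.971,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
SriLankan-2009,Asian,rs560887,G,599,515,NA,0.907,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
DGI-2009,Caucasian,rs560887,G,1464,1467,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
KORA-2009,Caucasian,rs560887,G,433,1438,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
Rotterdam-2009,Caucasian,rs560887,G,1178,4761,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
WTCCC-T2D-2009,Caucasian,rs560887,G,1924,2938,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA
CCC-2009,Caucasian,rs560887,G,512,499,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
ADDITION-ELY-2009,Caucasian,rs560887,G,852,1593,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
MAGIC-2010,Caucasian,rs560887,G,40655,87022,NA,0.70,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
UKADS-2011,Asian,rs560887,G,857,417,NA,0.82,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
DGP-2011,Asian,rs560887,G,821,1167,NA,0.84,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
RiyadhCohort-2017,Caucasian,rs560887,G,185,377,NA,0.81,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Shanghai-2008,Asian,rs16856187,C,1876,1800,NA,0.285,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
Shanghai-2010,Asian,rs16856187,C,3410,3412,NA,0.294,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
HongKong-2010,Asian,rs16856187,C,1342,1644,NA,0.298,NA,NA,NA,NA,NA,NA,NA,NA,NA,yes
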
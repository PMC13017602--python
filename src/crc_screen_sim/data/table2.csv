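label,strategy_type,colonoscopies_per_1000,qalys_gained_per_1000,efficient
FIT_only,reference,1243,156.77,yes
10%_74,risk_score,1268,159.73,yes
20%_74,risk_score,1294,162.05,yes
30%_74,risk_score,1320,164.12,yes
40%_74,risk_score,1346,165.96,yes
50%_74,risk_score,1373,167.69,no
60%_74,risk_score,1401,169.50,yes
70%_74,risk_score,1430,171.36,yes
FIT10_x,fit_based,1458,163.72,no
80%_74,risk_score,1460,172.88,yes
90%_74,risk_score,1489,174.25,yes
age_74,age_based,1519,175.55,yes
FIT10_74,fit_based,1654,176.92,no
60%_64:74,risk_score,1654,179.26,yes
40%_54:64:74,risk_score,1722,181.09,yes
70%_64:74,risk_score,1728,181.22,yes
80%_64:74,risk_score,1804,182.83,yes
50%_54:64:74,risk_score,1859,183.97,yes
90%_64:74,risk_score,1884,184.40,no
age_64,age_based,1965,185.69,no
60%_54:64:74,risk_score,2001,186.45,yes
FIT10_64,fit_based,2016,185.30,no
50/50,reference,2023,169.52,no
50%_54:64,risk_score,2032,186.96,yes
60%_54:64,risk_score,2161,188.89,yes
70%_54:64:74,risk_score,2169,188.98,yes
70%_54:64,risk_score,2290,190.33,yes
80%_54:64:74,risk_score,2339,190.80,no
80%_54:64,risk_score,2421,191.66,no
90%_54:64:74,risk_score,2515,192.82,yes
90%_54:64,risk_score,2559,193.26,yes
age_54,age_based,2696,194.56,yes
FIT10_54,fit_based,2698,194.50,no
COL_only,reference,2804,182.28,no
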
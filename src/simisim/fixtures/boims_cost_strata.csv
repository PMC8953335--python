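gender,age_band,expense_level,mean_2016,growth,mean_2017
1,1,1,33194.15,0.01119,33565.75
1,1,2,45858.05,0.01805,46685.56
1,1,3,62357.56,-0.01279,61560.03
1,1,4,138356.19,-0.01001,136970.70
1,2,1,38228.55,0.01782,38909.90
2,2,4,165315.70,-0.01338,163103.52
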
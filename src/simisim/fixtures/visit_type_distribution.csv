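gender,age_band,year,p_ooms,p_oims,p_boims
1,1,2016,0.115207,0.124424,0.760369
1,1,2017,0.113991,0.122510,0.763499
1,2,2016,0.063366,0.009901,0.926733
1,2,2017,0.063580,0.009231,0.927189
2,1,2016,0.133333,0.180000,0.686667
2,1,2017,0.128784,0.178859,0.692357
2,2,2016,0.036585,0.006098,0.957317
2,2,2017,0.036808,0.005730,0.957462
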
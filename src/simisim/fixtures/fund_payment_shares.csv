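gender,age_band,expense_level,r2014,r2015,r2016,mean_share
1,1,1,0.5270,0.5785,0.5660,0.5572
1,1,2,0.5377,0.5160,0.5822,0.5453
1,1,3,0.5438,0.5454,0.5663,0.5518
1,1,4,0.5781,0.4848,0.4924,0.5184
1,2,1,0.6142,0.6335,0.6435,0.6304
2,2,4,0.5750,0.6334,0.5848,0.5978
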
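gender,age_band,year,rate_pct
1,1,2011,0.1691
1,1,2012,0.1782
1,1,2013,0.2128
1,1,2014,0.1937
1,1,2015,0.6576
1,1,2016,0.6785
1,1,2017,0.6993
1,1,2025,0.8455
1,2,2011,5.5039
1,2,2012,6.7469
1,2,2013,7.1574
1,2,2014,9.7208
1,2,2015,7.3669
1,2,2016,7.4407
1,2,2017,7.5145
1,2,2025,8.0313
2,1,2011,0.0604
2,1,2012,0.1097
2,1,2013,0.1401
2,1,2014,0.1916
2,1,2015,0.4497
2,1,2016,0.4653
2,1,2017,0.4809
2,1,2025,0.5901
2,2,2011,8.4681
2,2,2012,8.0847
2,2,2013,16.3417
2,2,2014,11.8208
2,2,2015,7.6279
2,2,2016,7.6641
2,2,2017,7.7002
2,2,2025,7.9532
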
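year,urrbmi_fund,simis_fund,self_under_simis,total_self,total
2020,19.47,2.13,7.74,5.16,34.50
2021,20.94,2.16,8.49,5.40,36.98
2022,21.70,2.23,8.80,5.57,38.29
2023,22.18,2.32,9.03,5.70,39.23
2024,20.30,1.86,8.01,5.26,35.43
2025,20.31,1.76,7.97,5.13,35.17
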
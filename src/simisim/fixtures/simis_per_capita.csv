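year,beneficiaries,per_capita_payment,per_capita_self_under,max_payment,min_payment
2020,25267,8449,51072,33090,0.02
2021,28207,7641,49227,34585,0.49
2022,29259,7621,49106,37529,0.17
2023,29946,7749,49201,40647,58.36
2024,27056,6886,49036,41546,61.32
2025,27175,6489,48220,47449,2.09
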
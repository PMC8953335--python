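year,insured,uninsured
2016,3370900,435000
2017,3438500,436900
2018,3420400,439100
2019,3486800,441300
2020,3569900,443100
2021,3539700,444900
2022,3516400,446600
2023,3593800,448300
2024,3675000,450000
2025,3648600,451700
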
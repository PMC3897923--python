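year,volume
2012,650000
2013,714000
2014,783000
2015,860000
2016,944000
2017,1036000
2018,1137000
2019,1248000
2020,1370000
2021,1504000
2022,1651000
2023,1812000
2024,1989000
2025,2184000
2026,2397000
2027,2631000
2028,2888000
2029,3170000
2030,3480000
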
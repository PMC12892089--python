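year,otm,xhm,edm,official
2010,915,138,675,115
2011,2854,873,2615,218
2012,1108,222,869,99
2013,831,113,592,88
2014,393,16,153,82
2015,688,88,448,85
2016,780,98,541,141
2017,484,43,245,85
2018,1064,170,825,137
2019,892,118,653,159
2020,840,147,601,141
2021,381,20,141,241
2022,1729,422,1489,419
2023,2867,1002,2627,563
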
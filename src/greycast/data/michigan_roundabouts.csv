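year,total,X1,X2,X3,X4,X5,X6,X7,X8
2016,489,20,1,146,23,48,5,25,52
2017,1510,73,3,535,48,125,19,97,154
2018,1501,78,3,523,41,116,16,86,112
2019,1864,85,5,642,57,146,19,162,176
2020,1300,61,2,416,49,103,19,96,77
2021,1730,79,1,618,56,132,23,131,116
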
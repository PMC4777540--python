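site,class,aa_change,novel,TAS285,TAS286,TAS287,TAS288,TAS289,TAS290,TAS291,TAS292,TAS293,TAS294,TAS295,TAS296,TAS298,TAS338,TAS339,TAS340,TAS359,TAS360
chr4:60662207,nonsynonymous,E13Q,,5,,,,3,,,,4,,,,,,,,3,
chr4:60661804,nonsynonymous,D34E,,28,1,1,22,29,1,9,1,18,,,,1,15,1,,18,8
chr4:60661803,nonsynonymous,N35H,,28,1,1,21,29,1,9,1,18,,,,1,15,1,,18,8
chr4:60661769,nonsynonymous,H45R,,5,12,9,12,3,11,3,9,6,8,7,7,8,4,8,6,4,3
chr4:60661756,nonsynonymous,N50K,,,7,10,,,11,14,7,4,10,13,9,11,4,10,13,5,14
chr4:60661740,nonsynonymous,F56V,,28,34,20,21,27,19,28,21,23,16,14,17,17,21,16,13,21,28
chr4:60660909,nonsynonymous,A77T,1,6,,,,7,,,,4,,,,,4,,,3,
chr4:60660903,nonsynonymous,E79K,,4,,,,4,,,,2,,,,,3,,,3,
chr4:60660193,nonsynonymous,D110N,1,,,,19,,,,,,,,,,,,,,
chr4:60659762,nonsynonymous,E140K,,22,12,15,37,18,13,17,14,17,15,15,14,17,16,15,15,15,17
chr4:60659535,nonsynonymous,R161L,1,,5,10,,,8,7,9,3,8,7,7,9,4,8,7,3,7
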
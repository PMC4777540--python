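site,class,TAS285,TAS286,TAS287,TAS288,TAS289,TAS290,TAS291,TAS292,TAS293,TAS294,TAS295,TAS296,TAS298,TAS338,TAS339,TAS340,TAS359,TAS360
chr4:660662227,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660662222,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660662221,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660662214,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660662208,synonymous,3,5,,,,,,,,,,,,,,,,
chr4:660661848,synonymous,,1,1,,1,1,,,1,,,,1,,,,,1
chr4:660661845,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660661831,synonymous,18,,,,20,,,,11,,,,,12,,,11,
chr4:660661794,synonymous,,,1,,,1,,,1,,,,,,,,,
chr4:660661792,synonymous,,,1,,,1,,,1,,,,,,,,,
chr4:660661788,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660661782,synonymous,,,1,,,,,,1,,,,,,,,,
chr4:660661774,synonymous,,,1,,,,,,1,,,,,,,,,
chr4:660661748,synonymous,1,,,,,,,,1,,,,,,,,,
chr4:660661746,synonymous,,,,,,,,,1,,,,,,,,,
chr4:660660943,synonymous,24,47,38,12,20,45,12,36,30,39,40,40,38,27,37,40,27,13
chr4:660660209,synonymous,11,,,,13,,,,7,,,,,8,,,7,
chr4:660660191,synonymous,,5,10,,,8,,,,9,4,0,9,,4,3,,
chr4:660659782,synonymous,,,1,,1,,,1,1,,,,,1,,,,1
chr4:660659774,synonymous,,,,,,,,,1,,,,1,,,,,1
chr4:660659750,synonymous,,,,,,,,,,,,,1,,,,,
chr4:660659542,synonymous,,,,,,,,,1,,,,,,,,,
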
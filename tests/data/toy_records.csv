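mating_id,dam_id,sire_id,mating_date,birth_date,born,weaned,males_weaned,females_weaned,stock
M1,D1,S1,2010-01-01,2010-02-01,6,6,3,3,BW
M1,D1,S1,,2010-03-05,5,3,1,2,BW
M1,D1,S1,,2010-04-06,4,5,2,3,BW
M1,D1,S1,,2010-03-05,5,3,1,2,BW
M2,D2,S2,2011-05-01,2011-06-10,4,4,2,2,BW
M2,D2,S2,,2011-13-40,5,5,2,3,BW
M2,D2,S2,,2011-09-15,6,4,2,2,BW
M3,D3,S3,,2012-01-20,5,5,3,2,BW
M3,D3,S3,,2012-01-20,5,5,3,2,BW
M3,D3,S3,,2012-03-01,3,2,1,1,BW
M4,,S4,,2013-04-04,4,4,2,2,BW
M4,,S4,,2013-05-20,5,4,2,2,BW
M5,D5,S5,,2014-06-01,6,,3,3,BW
M5,D5,S5,,2014-07-10,4,4,2,2,BW
M6,D6,S6,,2015-01-01,5,4,2,1,BW
M6,D6,S6,,2015-02-20,5,5,2,3,
M7,D7,S7,,2016-03-03,abc,4,2,2,BW
M7,D7,S7,,2016-04-30,4,3,2,1,BW
M8,D8,S8,,2017-05-05,-2,1,0,1,BW
M8,D8,S8,,2017-06-20,6,5,2,3,BW
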
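image_id,NT,TT,BV,BG
008-01,2295,1221,1331,630
008-02,2187,138,1000,7444
010-03,10626,0,2332,3972
012-01,4516,855,8697,1685
012-02,6553,3139,6041,8731
014-01,0,30,64,1866
015-01,1251,2046,4089,696
016-04,1178,0,1064,956
016-05,2643,0,452,5125
017-01,1328,0,68,3069
020-01,1842,3655,1513,2625
025-02,977,1282,907,3687
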
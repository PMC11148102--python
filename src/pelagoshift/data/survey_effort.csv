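year,n_trawls,occ_pct_s_aurita,occ_pct_s_maderensis,occ_pct_c_chrysurus,occ_pct_c_rhonchus,occ_pct_b_auritus,occ_pct_s_dorsalis,occ_pct_t_trecae,occ_pct_s_guachancho
1995,158,43,36,19,32,28,16,27,20
1996,129,35,26,16,29,20,12,26,9
1997,115,47,41,22,23,20,13,26,10
1998,155,37,30,17,28,17,14,32,8
1999,164,38,34,20,23,21,23,38,7
2000,133,28,31,26,35,26,27,38,20
2001,115,41,45,26,29,26,20,24,18
2002,185,30,28,16,22,15,15,44,10
2003,175,30,30,17,22,19,14,38,10
2004,158,34,36,25,31,22,18,32,8
2005,131,39,34,30,25,28,23,43,24
2006,155,35,37,20,21,22,18,41,14
2011,281,14,7,8,19,17,12,19,9
2015,209,17,18,11,23,22,12,22,10
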
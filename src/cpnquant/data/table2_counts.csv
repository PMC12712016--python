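case_id,injected_area,total,ipsi,contra,pct_contra,homotopic,pct_homotopic
64FB,46d (r),15919,11804,4115,25.8,2374,57.7
60FB,46d (i),27710,24904,2806,10.1,1380,49.2
58FB,46d (c),21139,18676,2463,11.7,1272,51.6
48FB,12r (r),15157,11244,3913,25.8,427,10.9
48DY,12r (r),12629,10327,2302,18.2,460,20.0
52FB,46v (i),15240,13429,1811,11.9,667,36.8
52DY,46v (i),12600,10582,2018,16.0,1594,79.0
59FB,12r (i),15504,12311,3193,20.6,2076,65.0
30FB,45B,25591,23951,1640,6.4,799,48.7
56FB,GrFO,27857,22604,5253,18.9,1502,28.6
56DY,PrCO,11028,10256,772,7.0,162,21.0
42FB,DO,19703,18765,938,4.8,257,27.4
30DY,F5a,5729,5289,440,7.7,337,76.6
42DY,F5a,5346,4670,676,12.6,302,44.7
30CTBg,F5p,23019,20993,2026,8.8,551,27.2
18FB,F4,22695,18715,3980,17.5,1255,31.5
12DY,F2,16781,14702,2079,12.4,1767,85.0
11FB,F2,13166,11040,2126,16.1,1075,50.6
13FB,F7,23338,19440,3898,16.7,1864,47.8
11DY,F7,15211,12462,2749,18.1,1376,50.1
65FB,F3,7353,6291,1062,14.4,249,23.4
65DY,F6,18596,16003,2593,13.9,556,21.4
13TB,F1,2079,2030,49,2.4,3,6.1
62FR,F1,33812,33566,246,0.7,156,63.4
27DY,Opt,19080,17939,1141,6.0,436,38.2
27TB,Opt,7755,7128,627,8.1,358,57.1
29TB,PG,8580,7456,1124,13.1,895,79.6
29FB,PFG,17073,16281,792,4.6,271,34.2
29DY,PF,31273,30900,373,1.2,175,46.9
27FB,PF,12758,12645,113,0.9,69,61.1
74FB,AIP,6726,6106,620,9.2,266,42.9
74DY,AIP,16366,13900,2466,15.1,639,25.9
73DY,MIP,64758,61135,3623,5.6,974,26.9
72FB,MIP,23839,21927,1912,8.0,432,22.6
72DY,PEip,66017,62312,3705,5.6,1094,29.5
73FB,PEip,23528,20556,2972,12.6,458,15.4
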
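zip,state,lat,lon
02115,MA,42.3429,-71.0920
02215,MA,42.3473,-71.1030
01060,MA,42.3223,-72.6310
10001,NY,40.7506,-73.9972
11201,NY,40.6945,-73.9902
14604,NY,43.1566,-77.6088
06510,CT,41.3082,-72.9251
02903,RI,41.8211,-71.4111
03301,NH,43.2072,-71.5375
05401,VT,44.4759,-73.2121
04101,ME,43.6591,-70.2568
07102,NJ,40.7357,-74.1724
19104,PA,39.9597,-75.1997
15213,PA,40.4433,-79.9436
21201,MD,39.2946,-76.6252
20001,DC,38.9109,-77.0163
23219,VA,37.5407,-77.4360
27601,NC,35.7721,-78.6386
29201,SC,34.0007,-81.0348
30303,GA,33.7528,-84.3915
32801,FL,28.5421,-81.3790
33101,FL,25.7743,-80.1937
37201,TN,36.1659,-86.7844
40202,KY,38.2527,-85.7585
43215,OH,39.9612,-82.9988
48226,MI,42.3314,-83.0458
46204,IN,39.7684,-86.1581
60601,IL,41.8853,-87.6216
53202,WI,43.0445,-87.9073
55401,MN,44.9833,-93.2680
63101,MO,38.6270,-90.1994
66101,KS,39.1155,-94.6268
68102,NE,41.2587,-95.9379
73102,OK,35.4676,-97.5164
75201,TX,32.7876,-96.7994
77002,TX,29.7589,-95.3677
80202,CO,39.7392,-104.9903
84101,UT,40.7608,-111.8910
85004,AZ,33.4484,-112.0740
87102,NM,35.0844,-106.6504
89101,NV,36.1716,-115.1391
83702,ID,43.6150,-116.2023
59601,MT,46.5891,-112.0391
82001,WY,41.1400,-104.8202
98101,WA,47.6062,-122.3321
97201,OR,45.5152,-122.6784
94102,CA,37.7793,-122.4193
90012,CA,34.0522,-118.2437
99501,AK,61.2181,-149.9003
96813,HI,21.3069,-157.8583
58102,ND,46.8772,-96.7898
57101,SD,43.5446,-96.7311
50309,IA,41.5868,-93.6250
72201,AR,34.7465,-92.2896
70112,LA,29.9511,-90.0715
39201,MS,32.2988,-90.1848
35203,AL,33.5186,-86.8104
25301,WV,38.3498,-81.6326
19901,DE,39.1582,-75.5244
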
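case_id,age,sex,site,differentiation,neoadjuvant,t_class,n_class_clinical,m_class,dissection,pn_status,pn_class,n_positive_nodes,node_levels,mean_nuclear_area,mean_perimeter,circular_rate,aspect_ratio,nacv
1,65,M,tongue,well,C,2,0,0,Biopsy,0,0,0,,79.1,32.2,0.869,1.42,29.2
2,61,M,tongue,well,C,2,0,0,Biopsy,0,0,0,,54.6,26.4,0.874,1.37,30.6
3,82,F,tongue,well,C,2,0,0,Biopsy,0,0,0,,73.7,30.9,0.857,1.43,40.6
4,35,M,tongue,well,C,1,0,0,RND,0,0,0,,70.3,30.0,0.875,1.38,33.9
5,70,M,tongue,well,C,4,2b,0,RND,0,0,0,,78.0,31.9,0.861,1.46,33.5
6,57,M,tongue,well,C,3,0,0,SOHND,0,0,0,,48.0,24.8,0.843,1.48,45.0
7,78,F,tongue,well,C,2,0,0,SOHND,0,0,0,,61.3,27.7,0.888,1.29,33.1
8,80,F,tongue,well,C,2,2b,0,SOHND,0,0,0,,85.0,32.7,0.892,1.27,42.2
9,74,M,tongue,well,C,1,1,0,FND,0,0,0,,51.6,25.6,0.871,1.39,32.8
10,64,M,tongue,well,C,4,2c,0,RND,0,0,0,,50.6,25.4,0.862,1.43,36.6
11,52,M,tongue,well,C,1,0,0,FND,0,0,0,,76.2,30.7,0.893,1.30,46.1
12,56,M,tongue,well,C,2,0,0,SMND,0,0,0,,72.8,31.0,0.845,1.46,36.1
13,69,M,tongue,well,C,3,2b,0,SOHND,0,0,0,,68.1,29.4,0.883,1.31,35.5
14,74,F,tongue,well,C,1,1,0,SOHND,0,0,0,,43.3,23.2,0.892,1.33,23.8
15,61,M,tongue,well,C,2,2b,0,RND,0,0,0,,67.0,29.3,0.874,1.37,33.0
16,60,M,tongue,well,C+R,2,0,0,RND,0,0,0,,87.6,36.5,0.761,1.52,41.6
17,81,F,tongue,well,none,3,0,0,RND,0,0,0,,72.7,34.5,0.732,1.69,27.9
18,55,F,tongue,well,none,3,0,0,RND,0,0,0,,73.7,35.1,0.724,1.56,26.1
21,47,M,tongue,well,C,4,1,0,RND,0,0,0,,57.3,30.0,0.753,1.57,29.0
22,83,M,tongue,well,R,2,0,0,RND,0,0,0,,91.6,38.3,0.742,1.55,33.7
24,57,M,tongue,well,C,4,1,0,RND,0,0,0,,76.7,35.6,0.724,1.68,31.0
25,45,M,tongue,well,C+R,3,2b,0,RND,0,0,0,,76.9,34.3,0.784,1.61,32.1
19,61,F,tongue,moderate,none,4,0,0,RND,0,0,0,,95.9,38.1,0.787,1.42,41.0
20,72,M,tongue,moderate,none,2,0,0,SOHND,0,0,0,,101.4,39.9,0.765,1.49,27.6
26,82,M,tongue,moderate,C,3,1,0,SOHND,0,0,0,,79.2,33.9,0.808,1.37,39.9
23,59,M,tongue,poorly,C,2,0,0,RND,0,0,0,,76.3,32.7,0.858,1.43,21.8
27,79,F,upper_gingiva,well,C,4,0,0,SOHND,0,0,0,,131.4,44.5,0.800,1.35,30.3
28,63,F,upper_gingiva,well,C,2,0,0,SOHND,0,0,0,,123.3,42.3,0.834,1.25,23.0
29,53,F,upper_gingiva,well,C,2,0,0,SOHND,0,0,0,,48.7,27.2,0.796,1.35,25.9
31,69,F,upper_gingiva,well,C,2,0,0,SOHND,0,0,0,,56.3,30.3,0.741,1.75,29.9
32,84,M,upper_gingiva,well,C,4,0,0,SOHND,0,0,0,,55.7,29.1,0.800,1.32,22.3
30,74,M,upper_gingiva,moderate,none,2,0,0,SOHND,0,0,0,,53.8,28.3,0.816,1.22,23.9
33,81,F,lower_gingiva,well,C,2,0,0,SOHND,0,0,0,,107.4,40.3,0.791,1.31,29.7
34,74,M,lower_gingiva,well,C,3,0,0,SOHND,0,0,0,,72.1,33.8,0.771,1.68,22.8
35,74,F,lower_gingiva,well,C,2,0,0,SOHND,0,0,0,,51.7,28.2,0.784,1.45,30.7
36,81,F,lower_gingiva,well,C,4,0,0,SOHND,0,0,0,,65.4,31.0,0.823,1.30,30.8
37,68,M,lower_gingiva,moderate,C,1,0,0,SOHND,0,0,0,,61.7,30.1,0.820,1.27,29.5
38,68,F,buccal,well,none,2,0,0,SOHND,0,0,0,,62.3,30.4,0.820,1.43,24.3
39,60,F,buccal,moderate,C+R,2,0,0,SOHND,0,0,0,,93.9,38.6,0.772,1.68,27.5
40,63,M,mouth_floor,well,C,2,1,0,SOHND,0,0,0,,79.5,35.0,0.780,1.44,34.3
41,63,M,mouth_floor,moderate,C+R,4,0,0,SOHND,0,0,0,,80.3,35.6,0.757,1.45,38.4
42,76,M,mouth_floor,poorly,C+R,4,1,0,RND,0,0,0,,68.4,32.1,0.814,1.30,17.7
43,61,M,tongue,well,C,3,2b,0,RND,1,1,1,II,100.2,36.4,0.855,1.36,40.3
44,74,F,tongue,well,C,2,2c,0,RND,1,2c,1,I,121.2,40.6,0.830,1.47,41.8
45,71,M,tongue,well,C,2,2c,0,RND,1,1,1,I,102.6,36.6,0.871,1.35,40.2
46,71,F,tongue,well,C,2,0,0,RND,1,2b,2,II,72.0,30.0,0.891,1.29,41.1
47,58,F,tongue,well,C,4,1,0,RND,1,1,1,I,110.8,39.3,0.827,1.51,31.8
48,48,M,tongue,well,C,2,1,0,RND,1,2b,3,I+II,105.9,37.3,0.856,1.43,42.7
49,61,F,tongue,well,C,4,1,0,RND,1,2c,5,II,103.5,38.6,0.800,1.66,35.0
50,58,M,tongue,well,C,4,0,0,SOHND,1,1,1,II,71.5,30.4,0.873,1.41,35.1
51,58,F,tongue,well,C,2,0,0,RND,1,2b,2,I+II,110.4,38.4,0.857,1.40,37.8
52,67,M,tongue,well,C,4,1,0,RND,1,1,1,II,103.3,39.4,0.773,1.75,37.1
53,42,F,tongue,well,C,1,1,0,SOHND,1,1,1,I,140.3,44.3,0.825,1.47,46.8
54,69,F,tongue,well,C,1,0,0,RND,1,2b,3,II,61.2,28.1,0.866,1.42,30.7
55,69,F,tongue,well,C,3,1,0,RND,1,1,1,I,101.9,37.5,0.834,1.53,28.7
56,79,M,tongue,well,C,3,2b,0,RND,1,2b,3,II+IV,62.0,31.1,0.769,1.54,26.9
57,57,M,tongue,well,C+R,2,0,0,RND,1,1,1,II,67.2,32.1,0.766,1.54,36.5
58,49,M,tongue,well,C+R,2,1,0,RND,1,1,1,II,96.5,38.8,0.759,1.56,39.3
59,57,F,tongue,well,C+R,2,0,0,SMND,1,1,1,II,59.4,30.4,0.764,1.49,28.5
60,62,M,tongue,well,C+R,1,0,0,RND,1,2b,4,II+IV,67.6,32.9,0.750,1.64,30.2
61,45,M,tongue,well,C+R,4,2c,0,RND,1,2b,1,II,108.3,40.1,0.806,1.44,44.1
62,34,F,tongue,well,C+R,1,1,0,SOHND,1,1,1,II,83.1,35.5,0.798,1.47,31.2
63,62,M,tongue,well,none,1,0,0,RND,1,2b,4,II+IV,67.6,32.9,0.75,1.64,30.2
64,61,M,tongue,well,none,2,0,0,RND,1,2b,3,II,92.9,37.4,0.791,1.44,30.1
65,61,M,tongue,moderate,C,2,0,0,RND,1,1,1,II,86.1,35.3,0.839,1.39,27.1
66,57,M,tongue,moderate,C+R,3,2b,0,RND,1,2b,3,II+III,75.4,35.0,0.751,1.62,43.1
67,69,M,tongue,poorly,R,1,0,0,RND,1,2b,1,II,77.4,34.3,0.785,1.45,28.3
68,39,M,tongue,poorly,C+R,3,1,0,RND,1,2b,2,II+IV,85.0,36.8,0.757,1.44,23.1
69,44,M,upper_gingiva,well,C,1,0,0,SOHND,1,2b,4,II+III,135.5,44.9,0.796,1.29,33.6
70,65,M,upper_gingiva,well,C+R,4,0,0,RND,1,2b,4,II,120.1,43.9,0.745,1.39,41.2
71,81,F,upper_gingiva,moderate,none,2,3,0,SOHND,1,2b,2,II,196.0,54.8,0.788,1.28,28.9
72,84,M,lower_gingiva,well,C,2,2,0,SOHND,1,2b,3,II,127.0,43.0,0.831,1.30,25.0
73,64,M,lower_gingiva,well,C,2,1,0,RND,1,1,1,II,141.3,47.2,0.764,1.28,28.7
74,68,M,lower_gingiva,well,C,2,0,0,SOHND,1,2b,2,II,76.8,33.8,0.800,1.37,37.2
75,73,M,lower_gingiva,well,C,2,1,0,SOHND,1,1,1,II,72.4,33.1,0.778,1.37,49.5
76,75,M,lower_gingiva,well,C+R,4,0,0,SOHND,1,2b,2,II+III,89.5,34.1,0.789,1.35,35.7
77,59,F,lower_gingiva,moderate,C,2,1,0,RND,1,1,1,I,157.2,48.2,0.816,1.41,31.3
78,77,M,lower_gingiva,moderate,C,2,1,0,RND,1,1,1,II,150.1,46.8,0.831,1.31,26.3
79,76,M,lower_gingiva,moderate,C,2,1,0,RND,1,2b,3,III,126.3,43.4,0.798,1.51,41.6
80,66,M,lower_gingiva,moderate,C,4,0,0,RND,1,2b,2,II,119.6,42.4,0.793,1.25,35.7
81,62,M,lower_gingiva,moderate,C+R,4,2,0,RND,1,1,1,III,93.6,37.4,0.817,1.36,22.2
82,82,F,lower_gingiva,moderate,none,2,1,0,RND,1,1,1,III,103.5,39.6,0.795,1.33,28.5
83,53,F,buccal,well,C,4,1,0,SOHND,1,2b,2,II,90.7,39.6,0.696,1.42,33.6
84,65,F,buccal,well,none,2,0,0,SOHND,1,1,1,II,58.9,31.2,0.732,1.55,29.8
85,67,F,mouth_floor,well,none,2,1,0,SOHND,1,1,1,II,103.2,40.1,0.777,1.65,31.4
86,54,M,mouth_floor,moderate,C,2,1,0,SOHND,1,1,1,II,82.5,36.5,0.744,1.59,34.5
87,65,M,mouth_floor,moderate,C,3,1,0,RND,1,1,1,II,54.8,29.1,0.770,1.38,29.9
88,55,M,mouth_floor,moderate,C,2,0,0,SOHND,1,1,1,II,67.5,32.9,0.746,1.57,27.7
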
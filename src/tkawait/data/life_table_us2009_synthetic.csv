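age,qx
0,4.199911801239242e-05
1,4.5954263986125454e-05
2,5.0281865075718635e-05
3,5.501699344057087e-05
4,6.019802343781855e-05
5,6.58669424682401e-05
6,7.20696910667673e-05
7,7.885653498906908e-05
8,8.628247230046959e-05
9,9.440767875501521e-05
10,0.00010329799506325621
11,0.00011302545998004287
12,0.00012366889351667076
13,0.00013531453498061286
14,0.00014805674098816723
15,0.0001619987490746322
16,0.00017725351305331039
17,0.0001939446168472969
18,0.00021220727414617002
19,0.0002321894219230458
20,0.00025405291659630347
21,0.0002779748424360795
22,0.0003041489427063615
23,0.0003327871850062891
24,0.0003641214733350884
25,0.0003984055205621395
26,0.0004359168962440041
27,0.0004769592661084676
28,0.0005218648410201254
29,0.0005709970548765098
30,0.0006247534926593357
31,0.0006835690917992299
32,0.0007479196421118495
33,0.0008183256118518001
34,0.0008953563299075595
35,0.00097963455685679
36,0.0010718414805191978
37,0.001172722174806906
38,0.0012830915640967833
39,0.0014038409390469964
40,0.0015359450737766345
41,0.0016804699986305849
42,0.0018385814873876916
43,0.002011554322746467
44,0.002200782409259139
45,0.0024077898085935745
46,0.0026342427780858824
47,0.0028819629000207403
48,0.003152941395935027
49,0.0034493547274735414
50,0.003773581592924513
51,0.004128221436495494
52,0.0045161145956188475
53,0.004940364220032412
54,0.0054043601050042245
55,0.00591180458972429
56,0.00646674068045916
57,0.007073582566358705
58,0.007737148703591212
59,0.008462697650491235
60,0.009255966842252272
61,0.010123214497968935
62,0.011071264854970453
63,0.012107556924736418
64,0.013240196960450867
65,0.014478014817452589
66,0.01583062437333138
67,0.01730848815279773
68,0.018922986272078335
69,0.02068648977648413
70,0.022612438390670175
71,0.024715422631221617
72,0.02701127014241045
73,0.029517136004586386
74,0.03225159662645216
75,0.03523474666258353
76,0.03848829819046218
77,0.04203568113079725
78,0.04590214359411293
79,0.05011485047788966
80,0.05470297821378445
81,0.05969780306496242
82,0.06513277979045407
83,0.07104360681794808
84,0.07746827329036998
85,0.08444708246822841
86,0.09202264497456636
87,0.10023983426170113
88,0.109145695463426
89,0.11878929748528966
90,0.12922151680174954
91,0.14049474000912554
92,0.1526624707822083
93,0.16577882557802848
94,0.17989790132932393
95,0.1950729976142216
96,0.21135567556054824
97,0.22879463627352148
98,0.2474344031474699
99,0.2673137953740312
100,0.28846418468307233
101,0.3109075342859374
102,0.3346542285988786
103,0.35970071506919277
104,0.38602699571609045
105,0.4135940261159029
106,0.44234110356612444
107,0.4721833537618273
108,0.5030094557083977
109,0.5346797762841877
110,1.0
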
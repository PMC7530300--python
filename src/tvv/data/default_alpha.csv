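p,alpha,se,log_beta
1,1.0558107018818663,0.013984419573228277,2.9471190387020503
2,1.065658723583098,0.013393598862577202,3.363607100130296
3,1.0536002117485472,0.01656204762091556,3.6067956534990144
4,1.0665754596304517,0.015447930680844513,3.779170186705264
5,1.0701156003763939,0.014546066730040936,3.9120429711442095
6,1.0742491809642896,0.015471340359988874,4.02210492525507
7,1.0606681131806126,0.013829081414986915,4.114950814818732
8,1.05435571799652,0.015357555843167158,4.195070416288035
9,1.0506801540678,0.014387974305864965,4.265141974250214
10,1.0376726968271472,0.013606951957931455,4.327665182266506
11,1.0395375457282225,0.014272474566446921,4.3860762647210025
12,1.0421207988050383,0.015493451853892509,4.438338965010539
13,1.020629780813064,0.015746384321283117,4.487110909273582
14,1.023905632308005,0.014726336454872485,4.530851416081761
15,1.0094886419465683,0.01533316533304176,4.571927411319032
16,1.011326798939062,0.014197349188290334,4.611748131282612
17,0.9887993084204113,0.015562225289888088,4.64673477697638
18,0.9929113483904853,0.01640967833190041,4.682092089765147
19,0.9785613511903386,0.01538887173806865,4.7139083446443
20,0.9732220949172822,0.01485795280338941,4.7442862094196085
21,0.9755220150321096,0.014454715825848032,4.773243687236883
22,0.972717870041049,0.013420118235933006,4.801274697531123
23,0.9687615897004531,0.015519446729772375,4.828113536013845
24,0.9472582858200934,0.015354379730059353,4.853946650388095
25,0.9400024517325025,0.013998941274485262,4.878637065428105
26,0.9406964958737917,0.012544933481603513,4.900672576752033
27,0.9309220715798917,0.014657982898158367,4.924942560585266
28,0.9181761673091567,0.01455212770665295,4.946887096210438
29,0.9143632590178025,0.013979797935758332,4.9676929621607675
30,0.9109267876692237,0.01582210693456185,4.988372868702929
31,0.8979278014555848,0.013512689953813151,5.007292193047526
32,0.8990529349955277,0.01623933735836975,5.026402137621656
33,0.8949732889692963,0.01411367253361498,5.044998381144086
34,0.8771635310788922,0.014521447007392246,5.062740004693232
35,0.8798211808369674,0.015447290726584285,5.081551364815592
36,0.8772814098909678,0.015088937151095449,5.097621208546726
37,0.8681899814509657,0.014266641647481988,5.114188368709592
38,0.868896867715584,0.01378733118058463,5.129892177000428
39,0.8478254157870286,0.014139243356144244,5.146180737588986
40,0.8405824781843881,0.013565116547368933,5.160335950200417
41,0.8413505241438302,0.012874515719228789,5.175643476313004
42,0.846218026848413,0.01442633666717554,5.189094994724851
43,0.8210052773568801,0.01363210685319719,5.204998682393094
44,0.8185119250673772,0.013784063411660942,5.217502586295831
45,0.8177041095609278,0.013581328559533585,5.231042474820577
46,0.8025551618693519,0.013766423655289956,5.244276835722287
47,0.7938745204118404,0.015716428017089744,5.257394509350986
48,0.7914365224348622,0.013940002855157006,5.270561459461183
49,0.7908392910550637,0.014170383757116628,5.281985126322065
50,0.7794426868893072,0.013426862603183484,5.293783697291651
51,0.7738050731139015,0.014384514741779788,5.3064022507166175
52,0.7629064470909632,0.01540336241567262,5.317637604152419
53,0.7546999670397514,0.013330038470936252,5.328414219706241
54,0.7500972829632624,0.014362095946908373,5.340492452899929
55,0.7481888466586202,0.015057517739843568,5.351406805678558
56,0.7379380049813511,0.01391939168185727,5.363147593419042
57,0.7269030508283661,0.01721120621032089,5.372494800751092
58,0.7346712252967879,0.01603457064726036,5.383425291064392
59,0.7227425083947543,0.014986899007821249,5.3938307252155475
60,0.7201970844669155,0.013778393415323711,5.404299884256117
61,0.7016237501732241,0.014120162308877651,5.413346953231549
62,0.7049791354037286,0.0118401429984779,5.423413269164761
63,0.6942884802328694,0.015959551075631732,5.433196077561725
64,0.6842780309976255,0.01397234533978351,5.4420389956384225
65,0.6757115519871312,0.014569562553798206,5.4513790822594705
66,0.6792300777953333,0.016096397276501778,5.460614462261333
67,0.6757671070210073,0.01376280249119857,5.469911868004459
68,0.6605339545883173,0.01404166719413042,5.478324257558458
69,0.6514951261708751,0.014181065826292312,5.486925199399694
70,0.6404086263888452,0.015009364144277835,5.496435883586303
71,0.6389046282913527,0.015057087648198377,5.504613454330346
72,0.6396347721837947,0.015766906992997355,5.512493256511466
73,0.6262370541156524,0.015392881344461573,5.520403703629804
74,0.6213547308379556,0.014534438239276273,5.528092707079156
75,0.6175172190449832,0.015990594541810805,5.53713897273077
76,0.6195523803033494,0.015768806709041433,5.54462925218368
77,0.5985083199131546,0.016009198864505143,5.552489394648595
78,0.5916848228458985,0.01631610550322209,5.561567398928959
79,0.5838255880810215,0.013572849861373026,5.569318161815593
80,0.5884457598042024,0.014224112501376954,5.576171720821403
81,0.5655738413508647,0.014520592845990015,5.58398018032786
82,0.5677602811433424,0.014137716621072152,5.5905779197121594
83,0.5694533118233605,0.014147849581276257,5.598192037964716
84,0.5513733607472514,0.014216503429305069,5.605141026623667
85,0.5457944536515691,0.013721094277765848,5.612498426090616
86,0.5440980307921687,0.016267160462333737,5.620071107063983
87,0.5336465779107838,0.01461574836150706,5.626472062190951
88,0.520805279331952,0.01371141044854063,5.634032566010627
89,0.5151780625203537,0.015407830191176291,5.640664239649534
90,0.5218660720010588,0.014501685707860063,5.646861610435589
91,0.5091594500428935,0.014179012811011653,5.653565098954752
92,0.5074381079024302,0.013773432113002006,5.660609624967188
93,0.49500968572403664,0.014093144670468672,5.6666382514083615
94,0.49740156054667783,0.015372473129303864,5.673694696437624
95,0.4812913415036697,0.01486813981561983,5.679018638515043
96,0.47675701287418065,0.0145341192367646,5.685605674304332
97,0.4636255802628863,0.01513138542667065,5.6918533087783585
98,0.46815739771229575,0.01466589804271627,5.698196014655148
99,0.4530538863008713,0.01379264346642502,5.703455107685515
100,0.44093283790760157,0.014422694547599892,5.709412009598661
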
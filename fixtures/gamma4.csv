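timestamp
0.7138609036138969
1.1772519093093161
2.9319806310210277
4.0004594407145015
4.794169730259974
5.681711020676689
6.475179781743384
7.363181341957374
8.654269765317638
9.321950109529478
10.085485042458263
11.442866299797242
12.40338031263858
13.048985228864147
14.817709046709325
16.39877072381551
16.645495289627675
17.756820421999272
18.476721833605733
19.356997481046044
19.57545533659873
20.190153361655433
21.595145794353574
22.356286640139576
23.817272553294874
24.916825976338966
25.418758708222104
26.14547430954423
27.313526364889942
27.922762549396133
29.554307914800802
30.78274272341934
31.16102026856059
32.56764811447966
33.486306223068404
34.296733382267156
35.84826133046822
37.257378933529665
38.108910618757804
39.39052295559229
40.449919565622004
40.88694289315585
42.51250620323007
43.81780151633958
45.13508929334614
46.29199627383436
47.825748211818414
49.94330469619881
51.45937759317781
52.20677761029469
53.551061024279655
54.523491269631
55.52787554186338
56.21891793586377
57.05880398562121
58.36593372923714
58.59589824560028
59.84292930183869
60.589893009720264
61.88702662010462
62.78329492130927
63.90697232478533
64.3781833083178
65.5771546781648
66.8648975828822
67.6229886558273
68.05255532024724
69.37945479294652
70.31417312511687
70.48341404036562
71.80733319758929
72.54337854602898
74.8930223636016
76.25385663392515
76.98241602767614
78.50511313009032
78.96155728444198
81.35291395150765
82.34849334879877
83.13469843881832
83.77532992409856
84.71830615688535
85.12280531580043
85.71979789620453
86.92592088470543
87.93056951682519
88.3716601637976
89.46741166858746
90.17957176739648
91.60508090309527
93.47822413090552
95.30654585154194
95.92550679815773
96.96112522973945
98.77321140338805
99.21984146020868
99.69703926688969
100.23028452822236
100.6423757327205
101.97310378821992
103.73972184196309
104.32488245017592
104.70979468092973
105.411630397721
105.9051589243224
107.32477273744479
107.97026377440191
109.11823756244844
109.6028797267779
110.43345137196093
111.63365211884238
112.53595958890037
113.18023796631509
115.05030680869207
116.21213321485124
117.25706458265168
119.2073900368554
120.65748396568867
121.84341952452796
123.65642116923567
124.21360542510402
126.87183585984603
127.74324565949088
128.43319476706014
129.18557956911584
129.97828458636133
130.3933681224208
131.0795199546138
132.51520084658657
133.96490284273008
134.57063737119248
135.29660673857495
136.76840880278502
138.00576203816664
138.51569734299582
139.41293706404605
140.58546111784742
141.5553364615866
142.9957753529726
143.2132342017382
143.43523892966465
145.28816298675414
146.0370690685462
147.44404110212048
148.97137801719614
149.5128222513403
150.14637769907
150.92470833576252
153.09574595928808
153.73952143005818
154.86343538720638
155.2539184864011
155.75092912092242
156.08064434181264
157.49144687851165
158.4820759206142
160.39601653430816
160.90530659685723
163.07767814076445
163.8698112821317
164.57183001366207
164.89543797458518
166.55186523170946
167.34090683666523
168.32047341620586
169.20917035172312
170.2567117728556
171.2576780830396
173.05878621960224
173.77902755058102
175.58326131627038
175.91267106699956
177.3395312722634
178.89675649264663
181.15908952491446
181.9347620403293
182.71553085175208
183.76836219588654
184.64324665170818
185.9452331240908
187.4164604610435
188.0830790486829
188.3928847619528
189.26875589094468
190.08325627863678
190.95046345438425
191.57186678424733
192.32586201245408
193.54420282118807
195.8031847423604
196.58840032113386
198.18685860005672
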
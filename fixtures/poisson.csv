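timestamp
0.0662129802775638
0.3031484367642046
0.563861948589877
2.976673659640103
3.511048308496545
4.447410781445672
4.81876253591759
5.1951624402759755
6.801282892818774
7.048534031967735
7.090804218449991
7.311051180756641
9.065278106894892
11.111255454917886
11.456358064239627
12.655934114984404
12.984508101476802
13.209787741323272
13.360135892190318
13.39272581866601
13.931428382769004
14.395935965215271
14.585241613751286
14.83316983768163
15.007429599346443
15.57693328586681
16.742750403227372
17.071807529308916
19.199660410873943
20.31406077382699
20.73542950723413
21.885413222023747
22.610001312656674
24.7264732768301
25.529137856726766
25.708175388928424
27.404110586170695
28.028474762165697
28.71815732219559
29.92771038027125
30.547101450883144
30.989973971958644
31.07183090584551
31.799302585672784
32.85568484496234
33.86611334745282
35.24108885706336
39.424438767391266
40.529246210263686
40.97523848535782
41.11426143696341
44.406539411989186
44.70353346691555
45.39989498445839
48.0961802275754
48.1902832224853
48.62365825437261
49.17947008577324
50.85756921186195
52.219663966998624
53.06845291347234
56.75219953315986
57.16537368635993
57.30602487535403
58.25737956858014
58.682352821281235
62.311973047498434
63.43946256745973
64.8239309367904
65.6035768442344
65.63144839126893
67.4306293286363
67.45089571811856
69.47922896925725
69.63975968030763
72.25988974041219
72.59606095112103
73.16844804197098
73.20178498686576
73.98174019070953
74.09256142288156
76.34614046184666
77.71233427255135
81.88188691801908
82.4886552510081
83.09126002728568
83.97379432725424
85.0043440577419
85.22580458494322
90.3979600867221
91.11992478349795
91.8407493986345
92.08103433636883
92.2034157557451
92.67174181564928
92.70974775783117
94.36756099533264
96.30883404197473
96.58271318978757
100.11417085104567
100.74347702759619
100.89712208184824
103.29331534016696
104.16059805836417
104.32851718755079
105.37770959549894
106.24784750586764
106.94137675719811
107.21557140049303
107.35825264900264
108.70923473325314
110.1960027479927
110.57801530954885
114.48460889896799
115.15810043271672
115.54700011961096
117.4546335741151
118.83436642922766
118.91395496169763
119.85161544174758
123.45448778677073
125.12525082094183
127.5677371142892
128.0768887941915
128.11367744276274
131.00311586011742
133.6751648764316
133.9314401723911
134.2257463734126
134.67751479327268
136.01660307835928
137.2742021590079
138.47388892081418
139.84652056304142
141.24214499400918
143.59048911987665
144.1013427159981
144.21042456964187
144.99661409782604
146.0468681233776
146.78201297093116
147.30466143993013
148.36767200927562
149.5120385802497
150.58301621684652
151.78060196221804
151.86642926855848
152.04981292356842
152.64223965257474
153.98252524626335
154.11833219133393
154.29115012597677
154.63572314446319
155.81169839707223
157.38371933582928
157.9610366581407
158.87411928860257
159.5842870608727
160.02078640270426
160.02650132379935
160.23812041512375
160.8998652537625
161.2830297542969
162.1903632721418
163.2766426925886
164.56228813892824
165.73687201060767
166.21134200775532
166.46288250937644
166.74546697969097
167.0863431680811
167.8686374421315
168.34531924677734
168.35577738795612
169.57761127256381
172.60174186412596
172.83501749900296
175.55084201848678
175.7418660925817
176.58491209525576
176.87483088122138
176.9180256749268
177.4463892857063
178.20397139666738
179.39606395283883
179.6340271714082
182.05273760414048
182.07469488132637
184.65488130598817
185.7626283474891
186.48338753688176
186.86212026459083
188.44473135087068
192.1461480095978
192.65792438823686
193.0789119117959
194.55376669962243
196.26875433357642
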
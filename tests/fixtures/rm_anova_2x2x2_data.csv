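subject,time,condition,intensity,value
0,t1,c1,i1,0.5634938391287573
0,t1,c1,i2,-0.3424342419079174
0,t1,c2,i1,-0.6991535332562332
0,t1,c2,i2,0.9311862923547886
0,t2,c1,i1,-1.2424024285870399
0,t2,c1,i2,0.7505169816912239
0,t2,c2,i1,0.8182937514423047
0,t2,c2,i2,-0.07856527737452418
1,t1,c1,i1,-1.9398474417355849
1,t1,c1,i2,2.682948813990252
1,t1,c2,i1,-0.45970921766652173
1,t1,c2,i2,-0.4624495516535821
1,t2,c1,i1,1.4938209948918317
1,t2,c1,i2,0.8316159858607689
1,t2,c2,i1,-2.0810434246157916
1,t2,c2,i2,0.8891194437480889
2,t1,c1,i1,1.237471983590304
2,t1,c1,i2,-0.0075229487150888395
2,t1,c2,i1,-2.3051235395508436
2,t1,c2,i2,-2.0125784746900557
2,t2,c1,i1,0.6320744842995594
2,t2,c1,i2,-0.013203522958643969
2,t2,c2,i1,-0.9863103827441368
2,t2,c2,i2,1.8753761901577222
3,t1,c1,i1,1.0560650609301834
3,t1,c1,i2,0.12058005784676727
3,t1,c2,i1,-0.3086121996668544
3,t1,c2,i2,1.301049269656081
3,t2,c1,i1,0.3782841453450377
3,t2,c1,i2,0.8589254758992386
3,t2,c2,i1,-0.45545383177294835
3,t2,c2,i2,-0.6538888959182569
4,t1,c1,i1,1.9463175884266337
4,t1,c1,i2,0.3357810500741921
4,t1,c2,i1,-1.9724667782513747
4,t1,c2,i2,-1.2455980757996605
4,t2,c1,i1,-0.7211383388719668
4,t2,c1,i2,-1.069937588369116
4,t2,c2,i1,-0.3570014407046143
4,t2,c2,i2,-0.1382598690793025
5,t1,c1,i1,2.032441843969853
5,t1,c1,i2,0.9776176717481426
5,t1,c2,i1,0.8864123221440117
5,t1,c2,i2,1.832324875807118
5,t2,c1,i1,0.8200969971813585
5,t2,c1,i2,-1.0767498667007889
5,t2,c2,i1,-0.5494224574492611
5,t2,c2,i2,2.5009420597180174
6,t1,c1,i1,0.7070640024037967
6,t1,c1,i2,0.6203561564565331
6,t1,c2,i1,-0.31860245987423624
6,t1,c2,i2,0.09258015496872256
6,t2,c1,i1,0.1305132611121227
6,t2,c1,i2,1.1313592039666425
6,t2,c2,i1,-1.4446789741362687
6,t2,c2,i2,0.37199033982180807
7,t1,c1,i1,0.7776795861534888
7,t1,c1,i2,-1.3919386045603177
7,t1,c2,i1,0.38946369721572055
7,t1,c2,i2,-0.1307145208342581
7,t2,c1,i1,-2.410980246203636
7,t2,c1,i2,-0.7877924980332254
7,t2,c2,i1,-0.1256398581937484
7,t2,c2,i2,0.1442786873038449
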
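channel,A,B,C,D
Fp1,-0.873912464727,-1.45652077455,-1.90583181805,-0.284348456041
Fpz,-1.18705243437,-1.18705243437,-1.91788765222,-0.155483887908
Fp2,-1.45652077455,-0.873912464727,-1.90583181805,-0.284348456041
AF7,0.249628158585,-1.7473971101,-1.43073255402,-0.810045972541
AF3,-0.313482338917,-1.56741169459,-1.4801702171,-0.00983659072186
AFz,-1.00976711285,-1.00976711285,-1.49235760665,0.999991289494
AF4,-1.56741169459,-0.313482338917,-1.4801702171,-0.00983659072186
AF8,-1.7473971101,0.249628158585,-1.43073255402,-0.810045972541
F7,0.550527855897,-1.65158356769,-1.03768441797,-0.743275970622
F5,0.313482338917,-1.56741169459,-1.0065765315,-0.306710100892
F3,-4.81892568775e-18,-1.37005578977,-0.977584434256,0.628538331035
F1,-0.360651284091,-1.08195385227,-0.957306076699,1.79740502003
Fz,-0.733638750867,-0.733638750867,-0.950048129719,2.35996310246
F2,-1.08195385227,-0.360651284091,-0.957306076699,1.79740502003
F4,-1.37005578977,-1.28504685007e-17,-0.977584434256,0.628538331035
F6,-1.56741169459,0.313482338917,-1.0065765315,-0.306710100892
F8,-1.65158356769,0.550527855897,-1.03768441797,-0.743275970622
FT7,0.873912464727,-1.45652077455,-0.58556788711,-0.718111717301
FC5,0.661447693145,-1.32289538629,-0.490245935259,-0.213522575919
FC3,0.360651284091,-1.08195385227,-0.412451870754,0.8669291292
FC1,-4.81892568775e-18,-0.758683300264,-0.361675435517,2.21685334543
FCz,-0.385696716387,-0.385696716387,-0.344044251522,2.86645414619
FC2,-0.758683300264,-1.28504685007e-17,-0.361675435517,2.21685334543
FC4,-1.08195385227,0.360651284091,-0.412451870754,0.8669291292
FC6,-1.32289538629,0.661447693145,-0.490245935259,-0.213522575919
FT8,-1.45652077455,0.873912464727,-0.58556788711,-0.718111717301
T7,1.18705243437,-1.18705243437,-0.124547270325,-0.758688613424
C5,1.00976711285,-1.00976711285,0.0331488388591,-0.365420009151
C3,0.733638750867,-0.733638750867,0.158297179689,0.475670884151
C1,0.385696716387,-0.385696716387,0.238647360605,1.52579779243
Cz,-4.81892568775e-18,-1.28504685007e-17,0.266334146065,2.03096621318
C2,-0.385696716387,0.385696716387,0.238647360605,1.52579779243
C4,-0.733638750867,0.733638750867,0.158297179689,0.475670884151
C6,-1.00976711285,1.00976711285,0.0331488388591,-0.365420009151
T8,-1.18705243437,1.18705243437,-0.124547270325,-0.758688613424
TP7,1.45652077455,-0.873912464727,0.294608066854,-0.827147803609
CP5,1.32289538629,-0.661447693145,0.509036677948,-0.620444969223
CP3,1.08195385227,-0.360651284091,0.677256541135,-0.179241773488
CP1,0.758683300264,-1.28504685007e-17,0.784505946232,0.370980154144
CPz,0.385696716387,0.385696716387,0.821338972732,0.635526544426
CP2,-4.81892568775e-18,0.758683300264,0.784505946232,0.370980154144
CP4,-0.360651284091,1.08195385227,0.677256541135,-0.179241773488
CP6,-0.661447693145,1.32289538629,0.509036677948,-0.620444969223
TP8,-0.873912464727,1.45652077455,0.294608066854,-0.827147803609
P7,1.65158356769,-0.550527855897,0.625736348886,-0.876384184976
P5,1.56741169459,-0.313482338917,0.887798210893,-0.803101996565
P3,1.37005578977,-1.28504685007e-17,1.09222840814,-0.647150962744
P1,1.08195385227,0.360651284091,1.22211074708,-0.45299749079
Pz,0.733638750867,0.733638750867,1.2666424891,-0.359721432277
P2,0.360651284091,1.08195385227,1.22211074708,-0.45299749079
P4,-4.81892568775e-18,1.37005578977,1.09222840814,-0.647150962744
P6,-0.313482338917,1.56741169459,0.887798210893,-0.803101996565
P8,-0.550527855897,1.65158356769,0.625736348886,-0.876384184976
PO7,1.7473971101,-0.249628158585,0.832023046094,-0.897115957079
PO3,1.56741169459,0.313482338917,1.36139189649,-0.842441738036
POz,1.00976711285,1.00976711285,1.55865528437,-0.774177733206
PO4,0.313482338917,1.56741169459,1.36139189649,-0.842441738036
PO8,-0.249628158585,1.7473971101,0.832023046094,-0.897115957079
O1,1.45652077455,0.873912464727,1.6148719978,-0.886475844911
Oz,1.18705243437,1.18705243437,1.66879311157,-0.88294209915
O2,0.873912464727,1.45652077455,1.6148719978,-0.886475844911
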
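time_s,fz_left_n,fz_right_n
0.000000,-0.524611,-0.540809
0.005000,1.873949,1.931809
0.010000,-4.985939,-5.139886
0.015000,6.587647,6.791048
0.020000,6.436405,6.635136
0.025000,-7.155962,-7.376910
0.030000,-1.998360,-2.060061
0.035000,-15.837351,-16.326347
0.040000,3.120425,3.216772
0.045000,3.054046,3.148344
0.050000,6.427778,6.626243
0.055000,-3.349769,-3.453197
0.060000,4.030707,4.155159
0.065000,6.339064,6.534790
0.070000,3.463389,3.570325
0.075000,3.394158,3.498957
0.080000,-4.159895,-4.288337
0.085000,3.528116,3.637050
0.090000,-5.988970,-6.173887
0.095000,3.571353,3.681623
0.100000,-15.178833,-15.647497
0.105000,38.259389,39.440693
0.110000,63.437506,65.396213
0.115000,97.405170,100.412669
0.120000,126.497629,130.403392
0.125000,161.083271,166.056906
0.130000,185.730128,191.464764
0.135000,214.047453,220.656420
0.140000,253.988768,261.830970
0.145000,285.775787,294.599451
0.150000,310.663004,320.255090
0.155000,371.459042,382.928277
0.160000,430.891590,444.195875
0.165000,471.317745,485.870235
0.170000,532.624140,549.069537
0.175000,582.422986,600.405981
0.180000,627.091115,646.453291
0.185000,681.688920,702.736867
0.190000,726.801609,749.242464
0.195000,791.206941,815.636386
0.200000,838.020296,863.895158
0.205000,889.942886,917.420920
0.210000,911.806494,939.959592
0.215000,978.708057,1008.926819
0.220000,1021.867661,1053.419027
0.225000,1071.086235,1104.157283
0.230000,1111.581777,1145.903172
0.235000,1146.731573,1182.138259
0.240000,1184.709762,1221.289069
0.245000,1228.963175,1266.908859
0.250000,1260.316220,1299.229966
0.255000,1300.229787,1340.375911
0.260000,1317.862219,1358.552766
0.265000,1347.826201,1389.441920
0.270000,1378.810688,1421.383090
0.275000,1424.045555,1468.014637
0.280000,1439.681382,1484.133238
0.285000,1459.638661,1504.706722
0.290000,1487.021533,1532.935072
0.295000,1493.928892,1540.055704
0.300000,1517.492458,1564.346823
0.305000,1527.884573,1575.059807
0.310000,1550.703554,1598.583351
0.315000,1551.080482,1598.971917
0.320000,1563.675770,1611.956099
0.325000,1558.973651,1607.108797
0.330000,1564.535223,1612.842088
0.335000,1567.635649,1616.038244
0.340000,1567.151874,1615.539532
0.345000,1567.418070,1615.813947
0.350000,1578.082781,1626.807944
0.355000,1560.399481,1608.578651
0.360000,1537.877659,1585.361441
0.365000,1544.714536,1592.409415
0.370000,1509.927038,1556.547811
0.375000,1505.830931,1552.325232
0.380000,1483.166654,1528.961169
0.385000,1460.057376,1505.138365
0.390000,1447.195422,1491.879283
0.395000,1414.757939,1458.440254
0.400000,1394.271320,1437.321087
0.405000,1363.845437,1405.955769
0.410000,1322.310329,1363.138216
0.415000,1299.807610,1339.940700
0.420000,1277.214755,1316.650263
0.425000,1228.898989,1266.842691
0.430000,1195.407606,1232.317222
0.435000,1155.183737,1190.851394
0.440000,1109.602737,1143.863027
0.445000,1060.797954,1093.551338
0.450000,1027.910189,1059.648125
0.455000,982.258583,1012.586972
0.460000,937.466428,966.411807
0.465000,892.585496,920.145124
0.470000,835.204019,860.991925
0.475000,804.026358,828.851618
0.480000,747.425377,770.503015
0.485000,699.476286,721.073439
0.490000,651.115829,671.219796
0.495000,581.288603,599.236573
0.500000,550.264099,567.254151
0.505000,488.994713,504.093000
0.510000,431.546510,444.871017
0.515000,376.555682,388.182281
0.520000,324.577446,334.599156
0.525000,319.631057,329.500042
0.530000,319.857358,329.733330
0.535000,322.758100,332.723637
0.540000,310.364404,319.947270
0.545000,320.403848,330.296694
0.550000,303.820550,313.201366
0.555000,321.077144,330.990778
0.560000,315.482663,325.223561
0.565000,318.705946,328.546367
0.570000,322.538816,332.497582
0.575000,315.982274,325.738598
0.580000,308.405064,317.927433
0.585000,313.235264,322.906771
0.590000,306.246720,315.702448
0.595000,313.757490,323.445121
0.600000,324.714583,334.740528
0.605000,321.795880,331.731706
0.610000,319.052672,328.903798
0.615000,311.525181,321.143887
0.620000,312.208201,321.847996
0.625000,321.970813,331.912041
0.630000,321.475699,331.401640
0.635000,296.145394,305.289231
0.640000,323.770783,333.767586
0.645000,319.156944,329.011290
0.650000,306.742896,316.213944
0.655000,315.702474,325.450160
0.660000,318.843451,328.688118
0.665000,329.393145,339.563545
0.670000,325.217782,335.259264
0.675000,310.315168,319.896514
0.680000,327.876761,338.000341
0.685000,309.756960,319.321071
0.690000,318.840278,328.684846
0.695000,318.027099,327.846560
0.700000,331.580498,341.818436
0.705000,312.968850,322.632132
0.710000,327.774291,337.894708
0.715000,317.431131,327.232191
0.720000,324.627503,334.650759
0.725000,325.376921,335.423316
0.730000,315.677431,325.424343
0.735000,317.442499,327.243910
0.740000,319.995542,329.875781
0.745000,318.754884,328.596816
0.750000,327.658009,337.774835
0.755000,300.197081,309.466019
0.760000,316.503657,326.276080
0.765000,323.274510,333.255991
0.770000,319.280572,329.138735
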
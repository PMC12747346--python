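time_s,fz_left_n,fz_right_n
0.000000,1.196981,1.097277
0.005000,-3.842955,-3.522850
0.010000,7.491198,6.867208
0.015000,13.028992,11.943723
0.020000,16.710462,15.318540
0.025000,9.873567,9.051134
0.030000,9.501946,8.710468
0.035000,4.841451,4.438176
0.040000,14.578471,13.364136
0.045000,17.664967,16.193538
0.050000,-2.332661,-2.138359
0.055000,-3.523004,-3.229551
0.060000,16.406476,15.039875
0.065000,9.894171,9.070022
0.070000,-6.361193,-5.831329
0.075000,-2.271450,-2.082247
0.080000,2.606673,2.389547
0.085000,-0.164421,-0.150725
0.090000,3.047499,2.793654
0.095000,-5.043832,-4.623699
0.100000,-4.400147,-4.033630
0.105000,26.792572,24.560846
0.110000,73.660413,67.524763
0.115000,97.687244,89.550244
0.120000,145.163282,133.071697
0.125000,177.772799,162.964958
0.130000,205.699507,188.565470
0.135000,235.987126,216.330239
0.140000,277.409092,254.301902
0.145000,313.444409,287.335605
0.150000,343.785928,315.149783
0.155000,389.634590,357.179415
0.160000,453.402268,415.635473
0.165000,492.001812,451.019812
0.170000,548.164270,502.504138
0.175000,602.646953,552.448607
0.180000,658.243797,603.414432
0.185000,698.501568,640.318873
0.190000,741.505568,679.740793
0.195000,782.979472,717.760069
0.200000,836.079477,766.437032
0.205000,878.717465,805.523428
0.210000,952.810793,873.445045
0.215000,982.301272,900.479073
0.220000,1028.505039,942.834229
0.225000,1062.651233,974.136167
0.230000,1121.219224,1027.825653
0.235000,1152.503694,1056.504238
0.240000,1187.213957,1088.323260
0.245000,1240.449699,1137.124654
0.250000,1267.540697,1161.959068
0.255000,1309.369758,1200.303917
0.260000,1334.380385,1223.231248
0.265000,1370.544112,1256.382665
0.270000,1392.716666,1276.708324
0.275000,1416.744922,1298.735112
0.280000,1449.070131,1328.367746
0.285000,1475.956467,1353.014546
0.290000,1501.966638,1376.858163
0.295000,1532.315721,1404.679275
0.300000,1533.289327,1405.571783
0.305000,1550.340593,1421.202739
0.310000,1547.705675,1418.787301
0.315000,1581.937874,1450.168079
0.320000,1585.199197,1453.157746
0.325000,1593.749215,1460.995578
0.330000,1587.712512,1455.461711
0.335000,1598.815089,1465.639483
0.340000,1593.719644,1460.968470
0.345000,1581.720462,1449.968777
0.350000,1595.044834,1462.183276
0.355000,1584.818651,1452.808898
0.360000,1563.203373,1432.994096
0.365000,1573.808209,1442.715586
0.370000,1551.681698,1422.432135
0.375000,1545.914287,1417.145129
0.380000,1524.587516,1397.594802
0.385000,1522.711034,1395.874624
0.390000,1488.730191,1364.724265
0.395000,1449.375014,1328.647233
0.400000,1423.417980,1304.852329
0.405000,1410.848453,1293.329799
0.410000,1385.652765,1270.232821
0.415000,1356.445719,1243.458618
0.420000,1318.828007,1208.974328
0.425000,1283.722864,1176.793318
0.430000,1249.547716,1145.464839
0.435000,1220.013549,1118.390763
0.440000,1178.781534,1080.593228
0.445000,1144.930280,1049.561663
0.450000,1100.512826,1008.844025
0.455000,1050.116504,962.645537
0.460000,1014.447687,929.947805
0.465000,970.588846,889.742249
0.470000,933.437315,855.685309
0.475000,870.503844,797.993972
0.480000,815.169540,747.268819
0.485000,783.523545,718.258822
0.490000,725.298447,664.883668
0.495000,670.636483,614.774851
0.500000,620.121470,568.467558
0.505000,581.255442,532.838933
0.510000,510.145955,467.652613
0.515000,466.611675,427.744584
0.520000,424.716935,389.339526
0.525000,358.277632,328.434381
0.530000,328.245882,300.904168
0.535000,342.921420,314.357286
0.540000,332.357681,304.673469
0.545000,337.240239,309.149328
0.550000,344.768739,316.050730
0.555000,339.524042,311.242898
0.560000,339.638564,311.347880
0.565000,338.308763,310.128847
0.570000,326.020905,298.864524
0.575000,333.168595,305.416837
0.580000,331.234644,303.643977
0.585000,328.592869,301.222252
0.590000,324.451235,297.425602
0.595000,343.742581,315.110047
0.600000,329.920782,302.439555
0.605000,336.853968,308.795231
0.610000,334.833156,306.942746
0.615000,330.453683,302.928067
0.620000,325.569447,298.450671
0.625000,328.910252,301.513199
0.630000,326.431495,299.240913
0.635000,341.890693,313.412415
0.640000,327.208855,299.953522
0.645000,347.821160,318.848895
0.650000,339.174187,310.922184
0.655000,334.036330,306.212293
0.660000,352.680656,323.303612
0.665000,334.468812,306.608750
0.670000,333.669498,305.876016
0.675000,341.833756,313.360221
0.680000,339.294732,311.032688
0.685000,341.989835,313.503299
0.690000,334.834455,306.943936
0.695000,334.085017,306.256924
0.700000,324.379105,297.359480
0.705000,338.301125,310.121845
0.710000,338.827513,310.604387
0.715000,338.698928,310.486513
0.720000,336.664115,308.621192
0.725000,340.714515,312.334208
0.730000,345.280812,316.520149
0.735000,330.351656,302.834539
0.740000,357.606252,327.818924
0.745000,341.727118,313.262465
0.750000,342.426665,313.903742
0.755000,341.277529,312.850325
0.760000,337.307917,309.211368
0.765000,332.691812,304.979768
0.770000,338.214404,310.042348
0.775000,336.219418,308.213537
0.780000,344.649751,315.941654
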
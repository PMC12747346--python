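time_s,fz_left_n,fz_right_n
0.000000,-0.019730,-0.019694
0.005000,-5.072839,-5.063726
0.010000,-4.643402,-4.635060
0.015000,1.012354,1.010535
0.020000,-4.472187,-4.464153
0.025000,-9.472089,-9.455073
0.030000,-0.127887,-0.127657
0.035000,-1.290008,-1.287691
0.040000,-15.393648,-15.365993
0.045000,2.710068,2.705199
0.050000,-1.314025,-1.311665
0.055000,12.658344,12.635604
0.060000,-4.792222,-4.783613
0.065000,-10.302474,-10.283966
0.070000,-7.884966,-7.870801
0.075000,11.259159,11.238932
0.080000,4.943454,4.934573
0.085000,-0.878303,-0.876725
0.090000,-10.824835,-10.805388
0.095000,-5.326873,-5.317303
0.100000,0.113580,0.113376
0.105000,52.346726,52.252686
0.110000,89.794103,89.632790
0.115000,153.260066,152.984738
0.120000,185.471915,185.138719
0.125000,246.368311,245.925716
0.130000,268.403842,267.921661
0.135000,334.894568,334.292938
0.140000,372.651301,371.981842
0.145000,403.753090,403.027757
0.150000,476.525483,475.669416
0.155000,545.657141,544.676880
0.160000,642.549955,641.395629
0.165000,702.136870,700.875497
0.170000,792.652817,791.228835
0.175000,876.015567,874.441825
0.180000,935.980092,934.298625
0.185000,1025.380058,1023.537987
0.190000,1109.562682,1107.569378
0.195000,1170.722140,1168.618965
0.200000,1244.729325,1242.493198
0.205000,1329.675387,1327.286656
0.210000,1416.680095,1414.135062
0.215000,1450.592192,1447.986236
0.220000,1524.976349,1522.236764
0.225000,1575.817886,1572.986966
0.230000,1654.926402,1651.953365
0.235000,1690.818315,1687.780799
0.240000,1751.119741,1747.973895
0.245000,1809.948721,1806.697190
0.250000,1834.911000,1831.614625
0.255000,1893.300584,1889.899313
0.260000,1924.926159,1921.468073
0.265000,1947.231897,1943.733740
0.270000,1990.003781,1986.428785
0.275000,2024.249796,2020.613279
0.280000,2043.824460,2040.152776
0.285000,2078.128825,2074.395515
0.290000,2083.501591,2079.758629
0.295000,2101.838920,2098.063015
0.300000,2113.412495,2109.615799
0.305000,2133.878126,2130.044663
0.310000,2121.363751,2117.552770
0.315000,2104.923806,2101.142359
0.320000,2119.817445,2116.009242
0.325000,2095.411729,2091.647370
0.330000,2081.502922,2077.763550
0.335000,2048.689809,2045.009385
0.340000,2034.342508,2030.687858
0.345000,2012.826062,2009.210067
0.350000,1965.438544,1961.907679
0.355000,1942.617314,1939.127447
0.360000,1908.365948,1904.937613
0.365000,1859.959455,1856.618081
0.370000,1835.520478,1832.223008
0.375000,1789.891398,1786.675900
0.380000,1710.306834,1707.234307
0.385000,1650.622442,1647.657137
0.390000,1598.511325,1595.639636
0.395000,1564.411569,1561.601140
0.400000,1477.659276,1475.004696
0.405000,1421.811871,1419.257618
0.410000,1369.634268,1367.173752
0.415000,1293.476754,1291.153053
0.420000,1224.477701,1222.277955
0.425000,1142.762793,1140.709846
0.430000,1088.034117,1086.079488
0.435000,986.161894,984.390277
0.440000,901.055007,899.436283
0.445000,834.703980,833.204453
0.450000,780.632871,779.230482
0.455000,688.378585,687.141929
0.460000,589.892394,588.832666
0.465000,495.855679,494.964886
0.470000,470.715611,469.869982
0.475000,474.996965,474.143644
0.480000,475.960392,475.105340
0.485000,469.107455,468.264714
0.490000,460.438612,459.611444
0.495000,465.058576,464.223109
0.500000,473.970834,473.119356
0.505000,483.341646,482.473334
0.510000,479.902575,479.040441
0.515000,467.799381,466.958990
0.520000,468.073963,467.233079
0.525000,481.332716,480.468013
0.530000,480.350247,479.487308
0.535000,474.833494,473.980467
0.540000,448.786173,447.979939
0.545000,456.903981,456.083163
0.550000,477.017406,476.160455
0.555000,480.901571,480.037643
0.560000,474.545280,473.692771
0.565000,471.157499,470.311076
0.570000,470.016175,469.171802
0.575000,473.614523,472.763685
0.580000,456.413900,455.593963
0.585000,463.493106,462.660451
0.590000,475.546911,474.692602
0.595000,467.301173,466.461677
0.600000,468.543737,467.702009
0.605000,469.750047,468.906152
0.610000,473.454181,472.603632
0.615000,464.926397,464.091167
0.620000,459.941007,459.114733
0.625000,472.953658,472.104007
0.630000,453.848170,453.032842
0.635000,468.457588,467.616015
0.640000,456.617793,455.797490
0.645000,480.185719,479.323076
0.650000,492.460725,491.576031
0.655000,459.081903,458.257173
0.660000,478.704898,477.844916
0.665000,465.422041,464.585921
0.670000,464.284671,463.450594
0.675000,465.721658,464.885000
0.680000,473.515047,472.664388
0.685000,475.970963,475.115892
0.690000,463.461457,462.628859
0.695000,464.125067,463.291277
0.700000,480.510963,479.647737
0.705000,483.126146,482.258221
0.710000,460.110091,459.283514
0.715000,467.000027,466.161072
0.720000,479.628702,478.767061
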
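time_s,fz_left_n,fz_right_n
0.000000,-13.037898,-13.062778
0.005000,4.749495,4.758558
0.010000,-1.690998,-1.694225
0.015000,-10.497543,-10.517576
0.020000,5.144231,5.154048
0.025000,11.125062,11.146292
0.030000,5.281970,5.292050
0.035000,-2.391056,-2.395619
0.040000,-7.736101,-7.750864
0.045000,3.173522,3.179578
0.050000,2.547036,2.551897
0.055000,-5.688577,-5.699432
0.060000,4.612528,4.621330
0.065000,-13.522523,-13.548328
0.070000,12.196481,12.219756
0.075000,-10.402628,-10.422480
0.080000,4.288409,4.296593
0.085000,11.994789,12.017679
0.090000,-5.886328,-5.897561
0.095000,7.543659,7.558055
0.100000,-0.466655,-0.467545
0.105000,31.489060,31.549151
0.110000,58.741547,58.853644
0.115000,98.708013,98.896379
0.120000,131.874663,132.126321
0.125000,158.032808,158.334384
0.130000,196.157383,196.531712
0.135000,224.422336,224.850604
0.140000,255.525632,256.013255
0.145000,291.068429,291.623878
0.150000,320.390241,321.001645
0.155000,393.600331,394.351443
0.160000,470.348278,471.245849
0.165000,527.737695,528.744783
0.170000,607.544652,608.704036
0.175000,667.004540,668.277392
0.180000,735.940029,737.344432
0.185000,799.353439,800.878854
0.190000,882.326568,884.010322
0.195000,937.988593,939.778568
0.200000,1009.765211,1011.692158
0.205000,1067.597957,1069.635266
0.210000,1135.658849,1137.826039
0.215000,1201.437857,1203.730574
0.220000,1272.796173,1275.225064
0.225000,1325.077865,1327.606526
0.230000,1384.819546,1387.462213
0.235000,1446.259721,1449.019635
0.240000,1488.722373,1491.563319
0.245000,1549.597808,1552.554923
0.250000,1610.181635,1613.254363
0.255000,1650.766013,1653.916188
0.260000,1724.302898,1727.593404
0.265000,1758.198752,1761.553943
0.270000,1812.735305,1816.194568
0.275000,1849.528674,1853.058151
0.280000,1900.522816,1904.149605
0.285000,1936.204441,1939.899322
0.290000,1979.226140,1983.003119
0.295000,2025.676953,2029.542575
0.300000,2054.267786,2058.187968
0.305000,2092.235980,2096.228617
0.310000,2124.443070,2128.497169
0.315000,2144.405668,2148.497861
0.320000,2176.251192,2180.404156
0.325000,2198.267057,2202.462035
0.330000,2224.765358,2229.010903
0.335000,2235.202279,2239.467740
0.340000,2266.439278,2270.764350
0.345000,2269.167378,2273.497656
0.350000,2291.879154,2296.252773
0.355000,2301.238576,2305.630055
0.360000,2313.813968,2318.229446
0.365000,2308.703190,2313.108914
0.370000,2316.452513,2320.873026
0.375000,2311.084198,2315.494466
0.380000,2303.859809,2308.256291
0.385000,2309.203581,2313.610260
0.390000,2304.701625,2309.099714
0.395000,2292.236098,2296.610398
0.400000,2276.610445,2280.954926
0.405000,2255.800377,2260.105147
0.410000,2248.278702,2252.569118
0.415000,2229.727753,2233.982768
0.420000,2208.127801,2212.341596
0.425000,2189.083093,2193.260545
0.430000,2166.233931,2170.367780
0.435000,2140.195795,2144.279955
0.440000,2096.673550,2100.674655
0.445000,2067.095226,2071.039887
0.450000,2036.057328,2039.942759
0.455000,2008.151505,2011.983683
0.460000,1970.798723,1974.559621
0.465000,1900.639199,1904.266210
0.470000,1853.098856,1856.635145
0.475000,1832.183866,1835.680243
0.480000,1780.249987,1783.647258
0.485000,1723.689110,1726.978446
0.490000,1689.701216,1692.925692
0.495000,1621.708617,1624.803342
0.500000,1583.036291,1586.057217
0.505000,1512.079255,1514.964773
0.510000,1476.881180,1479.699529
0.515000,1410.957394,1413.649940
0.520000,1346.632165,1349.201958
0.525000,1288.838605,1291.298110
0.530000,1217.501829,1219.825202
0.535000,1159.335120,1161.547493
0.540000,1097.965283,1100.060542
0.545000,1028.445748,1030.408343
0.550000,974.187449,976.046502
0.555000,913.238699,914.981442
0.560000,836.169461,837.765133
0.565000,768.451190,769.917634
0.570000,697.586809,698.918022
0.575000,629.439471,630.640638
0.580000,560.041412,561.110146
0.585000,499.674326,500.627860
0.590000,416.826622,417.622057
0.595000,360.114830,360.802041
0.600000,326.011825,326.633957
0.605000,309.135920,309.725847
0.610000,331.128870,331.760767
0.615000,323.387824,324.004949
0.620000,316.424152,317.027988
0.625000,319.357882,319.967316
0.630000,317.523547,318.129481
0.635000,325.140932,325.761402
0.640000,319.325788,319.935161
0.645000,325.966057,326.588101
0.650000,319.821609,320.431929
0.655000,315.364618,315.966432
0.660000,327.529104,328.154132
0.665000,314.250763,314.850451
0.670000,329.437998,330.066668
0.675000,332.172129,332.806017
0.680000,326.288644,326.911304
0.685000,317.902805,318.509462
0.690000,317.315847,317.921384
0.695000,321.734560,322.348530
0.700000,314.597109,315.197458
0.705000,327.772112,328.397604
0.710000,335.881839,336.522806
0.715000,324.125020,324.743552
0.720000,321.311367,321.924529
0.725000,318.909874,319.518453
0.730000,325.138132,325.758596
0.735000,327.468934,328.093847
0.740000,319.722983,320.333114
0.745000,324.704976,325.324614
0.750000,312.932603,313.529776
0.755000,330.765087,331.396290
0.760000,330.711039,331.342139
0.765000,322.097067,322.711728
0.770000,319.008475,319.617242
0.775000,313.727674,314.326364
0.780000,317.893542,318.500182
0.785000,323.704169,324.321897
0.790000,313.609139,314.207603
0.795000,334.750922,335.389731
0.800000,328.660120,329.287306
0.805000,324.194592,324.813257
0.810000,332.800777,333.435865
0.815000,326.479908,327.102933
0.820000,315.651551,316.253912
0.825000,326.149033,326.771427
0.830000,316.945289,317.550120
0.835000,337.225696,337.869228
0.840000,322.282363,322.897378
0.845000,313.325550,313.923473
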
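time_s,fz_left_n,fz_right_n
0.000000,-2.870138,-2.269486
0.005000,1.355029,1.071454
0.010000,-9.566531,-7.564483
0.015000,-4.462733,-3.528788
0.020000,-5.089013,-4.024003
0.025000,-2.936234,-2.321749
0.030000,8.480322,6.705591
0.035000,1.395798,1.103691
0.040000,9.202611,7.276722
0.045000,-5.516873,-4.362322
0.050000,3.492254,2.761408
0.055000,5.337666,4.220619
0.060000,-9.785975,-7.738002
0.065000,-8.743971,-6.914065
0.070000,8.114181,6.416075
0.075000,-0.444283,-0.351305
0.080000,2.178117,1.722289
0.085000,2.216175,1.752382
0.090000,-10.957912,-8.664681
0.095000,-12.976775,-10.261043
0.100000,-5.434527,-4.297209
0.105000,30.262995,23.929666
0.110000,85.596275,67.683000
0.115000,115.986405,91.713195
0.120000,136.439698,107.886098
0.125000,178.068860,140.803262
0.130000,219.508014,173.570181
0.135000,255.489797,202.021828
0.140000,298.219787,235.809443
0.145000,331.514195,262.136119
0.150000,369.449838,292.132730
0.155000,435.804075,344.600596
0.160000,530.841998,419.749330
0.165000,602.149819,476.134112
0.170000,702.608077,555.568834
0.175000,784.049455,619.966459
0.180000,876.151309,692.793574
0.185000,944.825222,747.095662
0.190000,1015.779105,803.200577
0.195000,1110.546181,878.135147
0.200000,1173.291958,927.749717
0.205000,1263.060110,998.731520
0.210000,1330.480116,1052.042114
0.215000,1409.483991,1114.512347
0.220000,1479.851412,1170.153532
0.225000,1556.400930,1230.683048
0.230000,1623.566960,1283.792817
0.235000,1692.048511,1337.942800
0.240000,1768.832411,1398.657647
0.245000,1846.984562,1460.454402
0.250000,1902.992096,1504.740885
0.255000,1963.151292,1552.310185
0.260000,2013.065541,1591.778563
0.265000,2090.919966,1653.339899
0.270000,2124.622948,1679.989644
0.275000,2201.858620,1741.061718
0.280000,2253.308214,1781.744130
0.285000,2301.159385,1819.581183
0.290000,2344.369796,1853.748677
0.295000,2395.893077,1894.489355
0.300000,2448.584750,1936.153908
0.305000,2481.615696,1962.272258
0.310000,2520.326001,1992.881413
0.315000,2561.152955,2025.164251
0.320000,2586.189918,2044.961571
0.325000,2641.126503,2088.401229
0.330000,2651.998581,2096.998038
0.335000,2680.225924,2119.318066
0.340000,2681.710272,2120.491775
0.345000,2732.854326,2160.932589
0.350000,2739.588390,2166.257373
0.355000,2731.261922,2159.673438
0.360000,2765.422631,2186.685119
0.365000,2774.296687,2193.702045
0.370000,2782.890915,2200.497704
0.375000,2784.291501,2201.605180
0.380000,2800.104243,2214.108690
0.385000,2780.305547,2198.453393
0.390000,2775.990756,2195.041585
0.395000,2770.172117,2190.440649
0.400000,2753.866750,2177.547610
0.405000,2750.773061,2175.101357
0.410000,2728.634449,2157.595832
0.415000,2715.774680,2147.427309
0.420000,2680.536908,2119.563969
0.425000,2673.251617,2113.803317
0.430000,2631.586380,2080.857628
0.435000,2599.054164,2055.133635
0.440000,2573.133544,2034.637587
0.445000,2529.008861,1999.747156
0.450000,2513.744632,1987.677369
0.455000,2454.743418,1941.023713
0.460000,2398.826333,1896.808750
0.465000,2373.601965,1876.863245
0.470000,2304.835085,1822.487646
0.475000,2271.322084,1795.988123
0.480000,2221.944425,1756.944040
0.485000,2151.191521,1700.998044
0.490000,2094.688589,1656.319838
0.495000,2038.285250,1611.720384
0.500000,1979.713972,1565.406688
0.505000,1916.647028,1515.538163
0.510000,1859.950876,1470.707174
0.515000,1781.110515,1408.366235
0.520000,1716.348302,1357.157220
0.525000,1653.253458,1307.266633
0.530000,1576.722350,1246.751675
0.535000,1496.947417,1183.671748
0.540000,1434.442197,1134.247391
0.545000,1332.725369,1053.817489
0.550000,1270.242042,1004.410444
0.555000,1198.161186,947.414404
0.560000,1127.917936,891.871405
0.565000,1030.279491,814.666375
0.570000,959.489634,758.691160
0.575000,882.378612,697.717650
0.580000,812.655513,642.585946
0.585000,720.833147,569.979828
0.590000,633.230131,500.710050
0.595000,539.186440,426.347478
0.600000,469.524541,371.264166
0.605000,384.272861,303.853645
0.610000,360.986207,285.440337
0.615000,363.882348,287.730384
0.620000,346.338913,273.858375
0.625000,357.275612,282.506282
0.630000,366.037912,289.434839
0.635000,359.202158,284.029647
0.640000,345.428384,273.138398
0.645000,365.692207,289.161483
0.650000,362.958310,286.999725
0.655000,347.623571,274.874184
0.660000,375.505564,296.921136
0.665000,358.262392,283.286551
0.670000,354.543321,280.345795
0.675000,363.442396,287.382503
0.680000,351.292038,277.774928
0.685000,354.094455,279.990865
0.690000,370.785898,293.189184
0.695000,364.644048,288.332678
0.700000,350.807404,277.391717
0.705000,354.705791,280.474263
0.710000,363.440277,287.380828
0.715000,357.322922,282.543690
0.720000,351.218628,277.716881
0.725000,368.133113,291.091565
0.730000,357.992253,283.072947
0.735000,357.069129,282.343010
0.740000,363.076160,287.092912
0.745000,363.880656,287.729046
0.750000,350.674423,277.286565
0.755000,366.967730,290.170068
0.760000,371.274894,293.575845
0.765000,354.891738,280.621296
0.770000,363.951019,287.784684
0.775000,358.853130,283.753662
0.780000,355.845845,281.375731
0.785000,362.125087,286.340876
0.790000,361.262986,285.659193
0.795000,360.148956,284.778303
0.800000,374.897138,296.440039
0.805000,369.441544,292.126172
0.810000,358.995852,283.866516
0.815000,357.230167,282.470347
0.820000,351.293152,277.775808
0.825000,362.893028,286.948105
0.830000,359.946622,284.618312
0.835000,357.908563,283.006771
0.840000,356.000925,281.498356
0.845000,367.520858,290.607440
0.850000,362.074911,286.301201
0.855000,364.197742,287.979774
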
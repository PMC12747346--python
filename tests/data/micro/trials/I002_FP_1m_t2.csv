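time_s,fz_left_n,fz_right_n
0.000000,-5.193991,-4.844597
0.005000,-14.277120,-13.316714
0.010000,-7.771610,-7.248822
0.015000,-0.670492,-0.625388
0.020000,-0.584028,-0.544741
0.025000,8.438745,7.871080
0.030000,3.821857,3.564765
0.035000,6.486915,6.050548
0.040000,-0.328437,-0.306343
0.045000,-5.708490,-5.324486
0.050000,3.938324,3.673397
0.055000,10.033898,9.358929
0.060000,9.854519,9.191616
0.065000,3.877149,3.616338
0.070000,-7.236099,-6.749335
0.075000,19.164974,17.875767
0.080000,-0.894383,-0.834219
0.085000,5.250994,4.897766
0.090000,-8.614373,-8.034893
0.095000,-0.717169,-0.668925
0.100000,-5.023319,-4.685406
0.105000,24.681273,23.020991
0.110000,79.990940,74.610036
0.115000,111.818866,104.296931
0.120000,159.030304,148.332507
0.125000,189.117654,176.395914
0.130000,236.222896,220.332437
0.135000,247.614577,230.957812
0.140000,301.462805,281.183728
0.145000,345.086414,321.872824
0.150000,375.182172,349.944073
0.155000,477.010319,444.922351
0.160000,570.048648,531.702092
0.165000,685.603766,639.483942
0.170000,772.005999,720.073991
0.175000,879.217985,820.073942
0.180000,963.254874,898.457760
0.185000,1065.682991,993.995649
0.190000,1174.176098,1095.190542
0.195000,1255.956787,1171.469932
0.200000,1351.613546,1260.691965
0.205000,1460.958197,1362.681120
0.210000,1554.189248,1449.640619
0.215000,1632.081733,1522.293360
0.220000,1748.581837,1630.956628
0.225000,1837.016003,1713.441924
0.230000,1910.002934,1781.519103
0.235000,2000.960687,1866.358226
0.240000,2090.955856,1950.299518
0.245000,2173.664377,2027.444326
0.250000,2260.430194,2108.373500
0.255000,2356.913387,2198.366373
0.260000,2414.598812,2252.171362
0.265000,2513.988429,2344.875147
0.270000,2582.765416,2409.025581
0.275000,2654.327976,2475.774204
0.280000,2739.119287,2554.861695
0.285000,2810.560286,2621.496936
0.290000,2880.210294,2686.461663
0.295000,2941.491786,2743.620816
0.300000,3011.850847,2809.246899
0.305000,3070.678413,2864.117198
0.310000,3134.073882,2923.248123
0.315000,3178.652094,2964.827607
0.320000,3246.929929,3028.512465
0.325000,3286.103655,3065.051017
0.330000,3356.302780,3130.527923
0.335000,3409.738087,3180.368694
0.340000,3446.923542,3215.052724
0.345000,3484.928304,3250.500947
0.350000,3530.880705,3293.362180
0.355000,3562.305238,3322.672818
0.360000,3601.459160,3359.192898
0.365000,3634.019047,3389.562517
0.370000,3657.602592,3411.559622
0.375000,3699.130124,3450.293642
0.380000,3710.865768,3461.239842
0.385000,3730.180158,3479.254974
0.390000,3741.486547,3489.800794
0.395000,3773.533528,3519.692010
0.400000,3768.085257,3514.610238
0.405000,3778.921728,3524.717751
0.410000,3783.894303,3529.355827
0.415000,3805.034510,3549.073955
0.420000,3801.666836,3545.932820
0.425000,3794.858195,3539.582190
0.430000,3792.668601,3537.539887
0.435000,3785.372428,3530.734519
0.440000,3778.266208,3524.106327
0.445000,3757.717739,3504.940132
0.450000,3747.264717,3495.190273
0.455000,3732.319898,3481.250776
0.460000,3702.292069,3453.242887
0.465000,3681.506191,3433.855252
0.470000,3653.247390,3407.497390
0.475000,3616.844309,3373.543105
0.480000,3588.382788,3346.996160
0.485000,3547.001180,3308.398247
0.490000,3510.677712,3274.518220
0.495000,3467.493831,3234.239272
0.500000,3425.422272,3194.997822
0.505000,3379.730637,3152.379814
0.510000,3332.870949,3108.672326
0.515000,3269.819556,3049.862332
0.520000,3228.886512,3011.682809
0.525000,3157.401406,2945.006429
0.530000,3099.892909,2891.366466
0.535000,3041.408983,2836.816691
0.540000,2982.474341,2781.846519
0.545000,2911.417145,2715.569264
0.550000,2853.685080,2661.720772
0.555000,2775.860608,2589.131468
0.560000,2697.371483,2515.922222
0.565000,2631.531460,2454.511185
0.570000,2552.793710,2381.070039
0.575000,2474.494271,2308.037719
0.580000,2406.525162,2244.640818
0.585000,2327.879287,2171.285365
0.590000,2220.264454,2070.909666
0.595000,2140.469614,1996.482539
0.600000,2057.588306,1919.176566
0.605000,1958.156401,1826.433338
0.610000,1873.556839,1747.524697
0.615000,1797.151827,1676.259367
0.620000,1705.203117,1590.495948
0.625000,1602.211300,1494.432279
0.630000,1522.041614,1419.655521
0.635000,1422.629973,1326.931193
0.640000,1315.766746,1227.256540
0.645000,1228.418451,1145.784070
0.650000,1126.090902,1050.339986
0.655000,1037.238886,967.464949
0.660000,951.221371,887.233739
0.665000,821.146279,765.908657
0.670000,739.502959,689.757395
0.675000,630.599955,588.180178
0.680000,543.391082,506.837752
0.685000,438.254660,408.773744
0.690000,371.164483,346.196650
0.695000,360.448324,336.201356
0.700000,379.551449,354.019434
0.705000,376.335593,351.019904
0.710000,380.475540,354.881362
0.715000,374.083912,348.919692
0.720000,384.739393,358.858390
0.725000,366.991117,342.304021
0.730000,381.327746,355.676241
0.735000,363.201951,338.769748
0.740000,369.277622,344.436715
0.745000,369.417618,344.567295
0.750000,380.271949,354.691467
0.755000,382.966662,357.204909
0.760000,375.857583,350.574050
0.765000,374.776597,349.565780
0.770000,379.735010,354.190646
0.775000,367.589914,342.862538
0.780000,359.819219,335.614570
0.785000,371.003278,346.046289
0.790000,374.545790,349.350500
0.795000,379.355380,353.836554
0.800000,362.546018,338.157940
0.805000,385.438282,359.510265
0.810000,365.230111,340.661476
0.815000,370.742797,345.803330
0.820000,373.748921,348.607235
0.825000,377.600636,352.199850
0.830000,362.273776,337.904011
0.835000,373.097124,347.999284
0.840000,378.789530,353.308768
0.845000,376.715269,351.374041
0.850000,373.659407,348.523743
0.855000,368.238147,343.467165
0.860000,376.909617,351.555315
0.865000,371.430791,346.445044
0.870000,388.354536,362.230346
0.875000,376.652828,351.315800
0.880000,369.901164,345.018313
0.885000,374.384923,349.200454
0.890000,371.135433,346.169554
0.895000,383.652111,357.844249
0.900000,373.823909,348.677179
0.905000,373.120124,348.020737
0.910000,382.626157,356.887309
0.915000,394.033002,367.526829
0.920000,365.196658,340.630274
0.925000,365.092296,340.532932
0.930000,374.589540,349.391306
0.935000,364.526781,340.005459
0.940000,367.783940,343.043512
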
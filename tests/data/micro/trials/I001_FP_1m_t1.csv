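time_s,fz_left_n,fz_right_n
0.000000,4.913811,4.521509
0.005000,-3.419634,-3.146622
0.010000,0.186330,0.171454
0.015000,22.034142,20.275008
0.020000,15.121529,13.914275
0.025000,15.168870,13.957837
0.030000,-8.684040,-7.990735
0.035000,-11.860565,-10.913656
0.040000,-15.344952,-14.119861
0.045000,6.404900,5.893554
0.050000,-11.350987,-10.444761
0.055000,-10.135803,-9.326594
0.060000,11.691316,10.757919
0.065000,-17.968732,-16.534167
0.070000,5.292444,4.869912
0.075000,-11.785646,-10.844719
0.080000,1.308214,1.203771
0.085000,23.375345,21.509134
0.090000,3.604646,3.316863
0.095000,-2.370677,-2.181410
0.100000,-1.963454,-1.806698
0.105000,46.875266,43.132898
0.110000,92.716060,85.313912
0.115000,130.453299,120.038334
0.120000,187.302773,172.349132
0.125000,258.197990,237.584306
0.130000,305.945379,281.519700
0.135000,348.828796,320.979445
0.140000,391.153391,359.924983
0.145000,446.661200,411.001230
0.150000,491.928199,452.654259
0.155000,707.646424,651.150246
0.160000,928.764571,854.615042
0.165000,1137.134456,1046.349357
0.170000,1331.743728,1225.421661
0.175000,1535.308044,1412.734066
0.180000,1730.626134,1592.458599
0.185000,1948.731309,1793.150969
0.190000,2157.639660,1985.380760
0.195000,2357.068105,2168.887489
0.200000,2554.784862,2350.819186
0.205000,2752.678806,2532.913924
0.210000,2948.127421,2712.758561
0.215000,3108.985747,2860.774484
0.220000,3295.619959,3032.508430
0.225000,3472.365816,3195.143475
0.230000,3660.518336,3368.274513
0.235000,3838.248624,3531.815395
0.240000,3983.651984,3665.610226
0.245000,4141.424349,3810.786561
0.250000,4281.567589,3939.741223
0.255000,4420.200075,4067.305744
0.260000,4559.918025,4195.869070
0.265000,4712.104683,4335.905642
0.270000,4819.224923,4434.473752
0.275000,4933.627194,4539.742519
0.280000,5050.594856,4647.371866
0.285000,5146.607216,4735.718912
0.290000,5249.869993,4830.737527
0.295000,5325.128211,4899.987375
0.300000,5405.848612,4974.263322
0.305000,5477.858778,5040.524432
0.310000,5528.663585,5087.273150
0.315000,5583.920224,5138.118279
0.320000,5639.018680,5188.817854
0.325000,5670.677866,5217.949474
0.330000,5691.926476,5237.501664
0.335000,5716.863478,5260.447778
0.340000,5752.573717,5293.307028
0.345000,5728.464731,5271.122825
0.350000,5716.286994,5259.917318
0.355000,5713.101920,5256.986530
0.360000,5701.822389,5246.607520
0.365000,5651.793098,5200.572404
0.370000,5610.845619,5162.894038
0.375000,5560.124237,5116.222085
0.380000,5494.415511,5055.759330
0.385000,5440.707926,5006.339583
0.390000,5378.774630,4949.350839
0.395000,5290.681385,4868.290671
0.400000,5198.214754,4783.206273
0.405000,5083.419562,4677.575954
0.410000,4991.809753,4593.279973
0.415000,4872.215242,4483.233497
0.420000,4737.565865,4359.334087
0.425000,4631.590705,4261.819637
0.430000,4510.205304,4150.125250
0.435000,4355.175867,4007.472856
0.440000,4210.081914,3873.962731
0.445000,4083.409742,3757.403650
0.450000,3914.776948,3602.233948
0.455000,3756.883125,3456.945852
0.460000,3588.348195,3301.866200
0.465000,3407.761194,3135.696675
0.470000,3221.854225,2964.631911
0.475000,3043.600120,2800.609032
0.480000,2865.788407,2636.993225
0.485000,2662.578702,2450.007118
0.490000,2466.511921,2269.593669
0.495000,2268.830019,2087.694044
0.500000,2074.643266,1909.010526
0.505000,1856.920553,1708.670084
0.510000,1672.389335,1538.871235
0.515000,1457.388380,1341.035254
0.520000,1232.112703,1133.744851
0.525000,1045.230683,961.782880
0.530000,799.529376,735.697564
0.535000,581.282569,534.874868
0.540000,495.160012,455.628055
0.545000,481.710113,443.251952
0.550000,483.098354,444.529360
0.555000,494.379452,454.909812
0.560000,499.936554,460.023253
0.565000,511.241109,470.425289
0.570000,493.992326,454.553593
0.575000,482.199014,443.701820
0.580000,494.973500,455.456433
0.585000,486.023259,447.220750
0.590000,483.763545,445.141445
0.595000,499.873420,459.965160
0.600000,501.805366,461.742865
0.605000,470.758839,433.174992
0.610000,499.275336,459.414825
0.615000,490.625203,451.455290
0.620000,494.232017,454.774148
0.625000,479.320093,441.052743
0.630000,478.534308,440.329693
0.635000,484.188663,445.532622
0.640000,494.189375,454.734910
0.645000,487.169752,448.275710
0.650000,485.207784,446.470380
0.655000,497.782646,458.041306
0.660000,480.906123,442.512149
0.665000,469.885087,432.370997
0.670000,493.245110,453.866032
0.675000,477.027449,438.943136
0.680000,490.404698,451.252389
0.685000,499.370592,459.502476
0.690000,480.166778,441.831831
0.695000,482.913876,444.359610
0.700000,475.013886,437.090330
0.705000,487.759083,448.817991
0.710000,480.838148,442.449601
0.715000,470.368228,432.815566
0.720000,485.837465,447.049789
0.725000,497.946980,458.192520
0.730000,475.773746,437.789525
0.735000,490.473257,451.315475
0.740000,481.458642,443.020557
0.745000,470.019917,432.495063
0.750000,501.793809,461.732231
0.755000,492.675603,453.341993
0.760000,489.465075,450.387783
0.765000,480.692640,442.315711
0.770000,470.013822,432.489454
0.775000,496.947689,457.273009
0.780000,481.211090,442.792769
0.785000,506.049064,465.647761
0.790000,481.063466,442.656931
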
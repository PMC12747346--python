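time_s,fz_left_n,fz_right_n
0.000000,1.741756,1.539211
0.005000,18.197879,16.081691
0.010000,-0.676511,-0.597841
0.015000,3.409384,3.012915
0.020000,4.334826,3.830740
0.025000,1.595080,1.409592
0.030000,-5.376881,-4.751617
0.035000,1.553633,1.372964
0.040000,-8.977149,-7.933218
0.045000,-8.206630,-7.252300
0.050000,2.166526,1.914586
0.055000,15.240786,13.468471
0.060000,0.253064,0.223636
0.065000,9.182689,8.114856
0.070000,-0.106904,-0.094473
0.075000,3.524484,3.114630
0.080000,-9.566747,-8.454252
0.085000,-7.038604,-6.220101
0.090000,18.791435,16.606223
0.095000,-5.026981,-4.442405
0.100000,-7.722821,-6.824752
0.105000,32.278407,28.524827
0.110000,70.785186,62.553744
0.115000,119.691626,105.772969
0.120000,136.048697,120.227914
0.125000,196.105434,173.300796
0.130000,231.087260,204.214667
0.135000,273.003729,241.256769
0.140000,302.011082,266.890925
0.145000,338.647868,299.267306
0.150000,397.190774,351.002396
0.155000,501.647939,443.312483
0.160000,614.606458,543.135322
0.165000,713.884054,630.868160
0.170000,825.732584,729.710088
0.175000,913.303878,807.097923
0.180000,1012.624834,894.869080
0.185000,1125.009892,994.185144
0.190000,1239.441409,1095.309690
0.195000,1346.619320,1190.024135
0.200000,1434.865344,1268.008236
0.205000,1543.658515,1364.150106
0.210000,1651.259126,1459.238095
0.215000,1748.628018,1545.284189
0.220000,1832.267033,1619.197020
0.225000,1940.931903,1715.225508
0.230000,2019.378225,1784.549493
0.235000,2116.048175,1869.977922
0.240000,2212.987555,1955.644450
0.245000,2311.764346,2042.934720
0.250000,2392.659772,2114.423008
0.255000,2481.132014,2192.607022
0.260000,2562.248271,2264.290461
0.265000,2641.339399,2334.184268
0.270000,2728.064112,2410.823969
0.275000,2799.597141,2474.038590
0.280000,2884.256171,2548.852821
0.285000,2933.402765,2592.284274
0.290000,3006.842201,2657.183611
0.295000,3077.280250,2719.430585
0.300000,3140.936536,2775.684431
0.305000,3205.658400,2832.879943
0.310000,3250.328144,2872.355147
0.315000,3324.888467,2938.245027
0.320000,3377.563087,2984.794239
0.325000,3426.491108,3028.032536
0.330000,3470.217213,3066.673835
0.335000,3501.621818,3094.426473
0.340000,3549.103257,3136.386407
0.345000,3574.201261,3158.565823
0.350000,3612.216495,3192.160355
0.355000,3644.038296,3220.281674
0.360000,3670.289003,3243.479749
0.365000,3684.654804,3256.174984
0.370000,3711.225449,3279.655791
0.375000,3725.294141,3292.088469
0.380000,3725.976495,3292.691473
0.385000,3746.387565,3310.728988
0.390000,3745.035759,3309.534380
0.395000,3750.010810,3313.930894
0.400000,3742.157884,3306.991167
0.405000,3748.043314,3312.192194
0.410000,3730.967988,3297.102518
0.415000,3709.462186,3278.097574
0.420000,3705.067551,3274.213981
0.425000,3693.526629,3264.015126
0.430000,3678.788222,3250.990614
0.435000,3646.732821,3222.662859
0.440000,3611.282453,3191.334931
0.445000,3590.836159,3173.266288
0.450000,3555.446562,3141.992064
0.455000,3511.994106,3103.592592
0.460000,3477.213284,3072.856350
0.465000,3425.017866,3026.730614
0.470000,3372.513247,2980.331633
0.475000,3331.630777,2944.203289
0.480000,3271.331080,2890.915701
0.485000,3220.805443,2846.265572
0.490000,3145.606989,2779.811769
0.495000,3104.104519,2743.135523
0.500000,3022.961292,2671.428251
0.505000,2966.437223,2621.477233
0.510000,2885.767163,2550.188103
0.515000,2822.529082,2494.303830
0.520000,2722.742773,2406.121435
0.525000,2671.915338,2361.204603
0.530000,2574.800679,2275.383179
0.535000,2507.999323,2216.349995
0.540000,2415.615145,2134.708955
0.545000,2338.054473,2066.167631
0.550000,2235.867857,1975.864055
0.555000,2136.478837,1888.032751
0.560000,2059.837899,1820.304206
0.565000,1953.612197,1726.431241
0.570000,1874.851834,1656.829734
0.575000,1754.650977,1550.606752
0.580000,1683.497913,1487.727910
0.585000,1550.158818,1369.894504
0.590000,1461.784315,1291.796864
0.595000,1362.949846,1204.455622
0.600000,1259.114409,1112.694963
0.605000,1151.315616,1017.431837
0.610000,1047.041913,925.283878
0.615000,948.064917,837.816683
0.620000,839.102026,741.524830
0.625000,740.651618,654.522987
0.630000,632.335286,558.802506
0.635000,519.656986,459.227300
0.640000,417.219533,368.702058
0.645000,376.782164,332.967054
0.650000,372.720737,329.377922
0.655000,384.196493,339.519189
0.660000,389.605309,344.299026
0.665000,366.801228,324.146778
0.670000,378.479983,334.467438
0.675000,379.501100,335.369811
0.680000,376.029808,332.302188
0.685000,375.807516,332.105746
0.690000,378.511097,334.494934
0.695000,388.376738,343.213323
0.700000,385.427509,340.607053
0.705000,385.528304,340.696127
0.710000,369.359611,326.407653
0.715000,381.393455,337.042109
0.720000,388.693909,343.493611
0.725000,380.479275,336.234237
0.730000,382.607106,338.114627
0.735000,371.735032,328.506842
0.740000,384.980131,340.211700
0.745000,376.820090,333.000570
0.750000,391.534079,346.003504
0.755000,388.208152,343.064342
0.760000,384.638057,339.909405
0.765000,384.263911,339.578766
0.770000,396.854651,350.705360
0.775000,392.477251,346.836997
0.780000,383.129331,338.576125
0.785000,379.902523,335.724554
0.790000,380.608680,336.348594
0.795000,374.168805,330.657597
0.800000,385.133231,340.346996
0.805000,378.417456,334.412183
0.810000,379.335459,335.223433
0.815000,371.308594,328.129993
0.820000,364.981135,322.538339
0.825000,386.151824,341.247139
0.830000,372.948523,329.579219
0.835000,374.313618,330.785569
0.840000,387.055511,342.045738
0.845000,380.712605,336.440434
0.850000,375.052108,331.438182
0.855000,382.082228,337.650786
0.860000,382.286404,337.831219
0.865000,392.687392,347.022701
0.870000,383.382823,338.800138
0.875000,381.053034,336.741275
0.880000,377.729911,333.804590
0.885000,386.869664,341.881503
0.890000,386.274167,341.355255
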
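# sva::ComBat(par.prior=TRUE) output for the synthetic two-site fixture in test_sensitivity.py (input regenerated from numpy default_rng(0))
6.529931,6.192452,6.997476,6.628838,5.560903,6.437251,7.854155,7.326410,5.404590,4.786457,5.716388,6.223576
3.764238,6.088810,4.820516,5.677526,5.550500,5.645374,6.822248,7.438678,6.072635,7.710795,5.667431,6.563005
7.407614,6.462796,5.400334,5.462236,5.655293,6.272076,5.178763,5.966174,6.036991,6.793435,6.694977,6.567232
5.650196,6.195430,7.163146,8.206689,4.684859,7.783333,7.902578,7.131397,6.529058,5.843685,8.147050,8.323429
8.421196,7.922722,6.670825,5.136567,6.204213,6.781712,4.856434,6.677078,6.721165,6.965877,5.061401,5.454265
5.895525,4.951790,8.265734,5.946109,6.607994,5.712808,8.177328,7.765542,6.957500,3.744129,6.505048,6.926499
7.521019,5.611631,8.361111,5.009169,5.408486,7.107127,6.402977,8.567893,6.440865,5.488937,6.003344,4.984332
4.946177,7.104110,6.929089,7.980701,5.295767,7.987972,6.013927,8.064407,5.719274,5.375281,6.736000,7.307054
6.569744,5.650342,4.710524,4.917023,6.818363,7.170981,6.156267,4.948354,7.235878,4.769821,5.611522,6.857922
3.848751,6.812336,5.587130,6.633815,6.117931,6.250955,7.148970,5.320095,7.872262,6.999268,7.429647,7.453043
7.276841,7.359569,6.345624,4.888327,6.046065,5.115956,4.701041,6.516299,5.561597,5.048255,5.226206,6.472078
6.792807,7.931514,6.242325,7.693525,7.907771,7.358412,3.611093,7.657691,6.616355,6.663351,6.877827,6.597198
6.748504,5.921282,4.063765,6.385870,5.236275,7.276640,6.012332,6.310453,5.235174,5.625129,6.430816,4.552935
6.727369,6.223576,4.889981,3.784413,6.830921,5.667237,5.733368,5.934436,8.331593,6.137156,6.545445,4.551077
8.247073,7.447336,7.489700,6.563808,7.319690,6.448175,7.055324,6.033209,4.510126,7.335671,4.184523,5.915795
6.157240,5.103561,6.965970,6.281991,5.680552,6.622106,5.795152,7.846266,6.630101,5.665450,4.173656,4.747303
7.614537,6.289894,5.931638,8.376937,4.656298,5.330727,5.799768,6.902026,5.451279,5.510911,4.569696,6.976468
7.297776,5.780843,6.446889,5.040742,5.638233,7.624498,6.503207,8.930194,5.307662,6.837256,6.215962,6.797518
6.379906,5.679432,5.257094,9.993713,6.115940,3.659115,5.596232,7.009906,5.641201,7.704109,7.614946,6.011652
5.855147,5.149064,5.450574,4.835635,7.668149,7.873019,4.893696,4.822103,4.167947,5.121534,2.816519,4.928379
7.730930,6.085558,7.163915,5.497659,8.197550,6.497476,5.700748,9.128171,6.098515,4.950462,6.233970,6.342871
7.470327,5.445488,7.107857,7.009621,5.495152,6.457249,5.196337,8.896836,5.672204,5.821886,4.813727,5.993387
6.258578,7.322956,5.516965,5.839325,4.661847,5.349480,9.227759,7.436194,5.585425,4.818669,4.914838,6.362370
6.304466,5.642493,4.756945,7.651529,6.740848,5.855852,5.882101,5.677495,3.166102,6.467087,4.808454,5.246663
5.541625,7.283518,4.887395,4.432400,6.950249,7.118263,5.052256,6.900060,6.135389,6.677674,4.595133,7.334309
7.625084,7.177690,6.830894,1.797748,6.528231,6.246251,5.964848,5.564358,6.525015,6.803399,5.712254,5.860090
7.655027,5.241304,7.361282,6.247918,5.343116,5.950439,5.096026,7.026206,6.853491,5.704219,4.772970,6.730188
7.347210,6.343199,6.673528,5.624931,6.313383,5.948984,6.460646,4.579978,7.186180,6.075028,6.409517,5.999997
6.627275,5.277759,7.540020,4.128971,5.081671,6.538234,7.774419,6.581779,6.184484,4.719186,5.793488,6.364433
8.175818,7.161078,4.484320,8.332619,5.798602,5.291267,7.787886,6.214669,6.050310,6.584075,6.954292,7.516783
4.711031,8.690633,7.267648,5.621355,5.327142,5.191127,6.268814,5.544834,5.604008,7.256199,6.416194,5.938284
7.095030,7.989284,4.972869,5.368830,7.287187,7.078646,6.384950,7.571870,5.240947,4.657872,5.037034,6.526411
5.365520,5.928257,5.107200,5.349518,5.120010,6.685617,7.023618,5.732452,6.230120,5.676724,6.602928,6.488325
8.066858,5.252300,6.610745,6.548998,5.837073,6.927230,4.513181,8.642672,4.955931,7.379346,4.751792,7.695965
5.830366,6.645763,6.263206,7.289072,5.880354,2.956713,5.275799,6.476069,5.968268,7.209195,7.145232,6.218975
4.581693,8.007939,7.420747,5.711517,8.584401,5.884582,4.851969,6.095856,7.673097,5.272384,8.193708,5.367399
7.343860,7.074771,6.030057,7.266308,4.569136,7.792782,6.058549,5.663046,7.304061,7.538273,6.870166,8.661121
7.486603,7.896076,5.596355,6.168711,6.864705,6.254865,6.469181,6.747461,7.410810,6.220605,5.615897,5.444976
5.257426,7.772660,6.108225,6.935467,4.794416,4.107389,4.950916,7.554186,7.662142,6.712554,5.109111,6.238274
5.928704,6.086335,3.386057,5.081886,6.026626,7.970419,6.310813,7.838867,6.020774,6.049213,1.639295,6.913995
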
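# Monte-Carlo null distributions of the dip statistic for uniform
# samples: 999 sorted draws each, generated by
# fretshift.stats.generate_dip_null(n, 999, seed=...) with
# seeds: 20240612 (n=200), 20240613 (n=500), 20240614 (n=1000).

DIP_NULL_N200 = [
    0.014790,
    0.015132,
    0.015162,
    0.015640,
    0.016521,
    0.016574,
    0.016589,
    0.016749,
    0.016749,
    0.016787,
    0.016832,
    0.016916,
    0.016931,
    0.017136,
    0.017265,
    0.017295,
    0.017348,
    0.017356,
    0.017386,
    0.017394,
    0.017417,
    0.017675,
    0.017842,
    0.017880,
    0.017925,
    0.018062,
    0.018221,
    0.018229,
    0.018426,
    0.018472,
    0.018730,
    0.018798,
    0.018836,
    0.018844,
    0.018867,
    0.018927,
    0.018943,
    0.018950,
    0.018950,
    0.018981,
    0.018988,
    0.019019,
    0.019064,
    0.019087,
    0.019094,
    0.019102,
    0.019125,
    0.019148,
    0.019216,
    0.019224,
    0.019307,
    0.019307,
    0.019375,
    0.019406,
    0.019451,
    0.019489,
    0.019489,
    0.019497,
    0.019504,
    0.019527,
    0.019573,
    0.019603,
    0.019656,
    0.019687,
    0.019694,
    0.019709,
    0.019709,
    0.019709,
    0.019717,
    0.019740,
    0.019740,
    0.019770,
    0.019785,
    0.019793,
    0.019800,
    0.019838,
    0.019854,
    0.019854,
    0.019876,
    0.019884,
    0.019884,
    0.019892,
    0.019899,
    0.019899,
    0.019907,
    0.019914,
    0.019914,
    0.019914,
    0.019930,
    0.019930,
    0.019945,
    0.019945,
    0.019945,
    0.019990,
    0.019990,
    0.019990,
    0.019990,
    0.019990,
    0.020021,
    0.020081,
    0.020081,
    0.020150,
    0.020150,
    0.020195,
    0.020203,
    0.020218,
    0.020226,
    0.020233,
    0.020241,
    0.020241,
    0.020248,
    0.020256,
    0.020271,
    0.020294,
    0.020294,
    0.020309,
    0.020332,
    0.020339,
    0.020339,
    0.020339,
    0.020355,
    0.020362,
    0.020370,
    0.020453,
    0.020453,
    0.020484,
    0.020491,
    0.020499,
    0.020499,
    0.020506,
    0.020544,
    0.020544,
    0.020560,
    0.020567,
    0.020582,
    0.020590,
    0.020605,
    0.020613,
    0.020628,
    0.020643,
    0.020658,
    0.020666,
    0.020689,
    0.020711,
    0.020742,
    0.020772,
    0.020780,
    0.020780,
    0.020787,
    0.020795,
    0.020802,
    0.020818,
    0.020825,
    0.020825,
    0.020840,
    0.020848,
    0.020848,
    0.020856,
    0.020856,
    0.020886,
    0.020894,
    0.020901,
    0.020901,
    0.020909,
    0.020916,
    0.020924,
    0.020932,
    0.020962,
    0.020970,
    0.020977,
    0.020985,
    0.021000,
    0.021000,
    0.021045,
    0.021045,
    0.021045,
    0.021045,
    0.021083,
    0.021091,
    0.021114,
    0.021137,
    0.021152,
    0.021152,
    0.021167,
    0.021174,
    0.021190,
    0.021190,
    0.021235,
    0.021281,
    0.021288,
    0.021296,
    0.021304,
    0.021304,
    0.021311,
    0.021326,
    0.021357,
    0.021395,
    0.021417,
    0.021433,
    0.021463,
    0.021463,
    0.021493,
    0.021501,
    0.021546,
    0.021554,
    0.021554,
    0.021562,
    0.021569,
    0.021569,
    0.021569,
    0.021584,
    0.021592,
    0.021592,
    0.021600,
    0.021607,
    0.021645,
    0.021645,
    0.021653,
    0.021691,
    0.021706,
    0.021721,
    0.021744,
    0.021751,
    0.021759,
    0.021767,
    0.021805,
    0.021805,
    0.021827,
    0.021850,
    0.021858,
    0.021880,
    0.021911,
    0.021926,
    0.021979,
    0.021979,
    0.022025,
    0.022055,
    0.022070,
    0.022123,
    0.022139,
    0.022154,
    0.022192,
    0.022199,
    0.022207,
    0.022207,
    0.022222,
    0.022222,
    0.022237,
    0.022260,
    0.022268,
    0.022283,
    0.022290,
    0.022306,
    0.022336,
    0.022344,
    0.022359,
    0.022374,
    0.022397,
    0.022404,
    0.022412,
    0.022419,
    0.022419,
    0.022442,
    0.022450,
    0.022457,
    0.022465,
    0.022473,
    0.022480,
    0.022488,
    0.022533,
    0.022541,
    0.022556,
    0.022564,
    0.022564,
    0.022579,
    0.022586,
    0.022586,
    0.022594,
    0.022602,
    0.022624,
    0.022624,
    0.022624,
    0.022632,
    0.022632,
    0.022632,
    0.022640,
    0.022655,
    0.022670,
    0.022723,
    0.022731,
    0.022738,
    0.022761,
    0.022776,
    0.022784,
    0.022791,
    0.022791,
    0.022799,
    0.022807,
    0.022822,
    0.022852,
    0.022860,
    0.022875,
    0.022882,
    0.022890,
    0.022890,
    0.022898,
    0.022905,
    0.022905,
    0.022943,
    0.022943,
    0.022958,
    0.022966,
    0.022974,
    0.022974,
    0.022989,
    0.022989,
    0.022996,
    0.023019,
    0.023027,
    0.023042,
    0.023042,
    0.023050,
    0.023057,
    0.023103,
    0.023110,
    0.023118,
    0.023125,
    0.023133,
    0.023148,
    0.023148,
    0.023156,
    0.023186,
    0.023186,
    0.023194,
    0.023247,
    0.023247,
    0.023270,
    0.023300,
    0.023330,
    0.023330,
    0.023346,
    0.023353,
    0.023353,
    0.023384,
    0.023406,
    0.023406,
    0.023437,
    0.023482,
    0.023513,
    0.023513,
    0.023535,
    0.023551,
    0.023604,
    0.023611,
    0.023649,
    0.023657,
    0.023664,
    0.023687,
    0.023702,
    0.023710,
    0.023725,
    0.023733,
    0.023740,
    0.023748,
    0.023771,
    0.023793,
    0.023801,
    0.023801,
    0.023809,
    0.023809,
    0.023824,
    0.023831,
    0.023839,
    0.023839,
    0.023854,
    0.023862,
    0.023907,
    0.023923,
    0.023930,
    0.023945,
    0.023960,
    0.023983,
    0.023983,
    0.023983,
    0.024006,
    0.024067,
    0.024082,
    0.024090,
    0.024105,
    0.024105,
    0.024105,
    0.024112,
    0.024112,
    0.024127,
    0.024150,
    0.024158,
    0.024165,
    0.024173,
    0.024181,
    0.024211,
    0.024211,
    0.024241,
    0.024249,
    0.024272,
    0.024287,
    0.024310,
    0.024340,
    0.024348,
    0.024378,
    0.024401,
    0.024401,
    0.024408,
    0.024408,
    0.024416,
    0.024431,
    0.024446,
    0.024515,
    0.024537,
    0.024553,
    0.024553,
    0.024553,
    0.024560,
    0.024591,
    0.024591,
    0.024628,
    0.024628,
    0.024651,
    0.024651,
    0.024666,
    0.024674,
    0.024682,
    0.024682,
    0.024689,
    0.024689,
    0.024704,
    0.024712,
    0.024720,
    0.024742,
    0.024765,
    0.024765,
    0.024788,
    0.024795,
    0.024803,
    0.024826,
    0.024833,
    0.024841,
    0.024879,
    0.024894,
    0.024909,
    0.024917,
    0.024955,
    0.024955,
    0.024963,
    0.025000,
    0.025016,
    0.025023,
    0.025031,
    0.025076,
    0.025099,
    0.025099,
    0.025107,
    0.025122,
    0.025122,
    0.025145,
    0.025152,
    0.025167,
    0.025183,
    0.025190,
    0.025213,
    0.025228,
    0.025251,
    0.025251,
    0.025259,
    0.025281,
    0.025281,
    0.025304,
    0.025312,
    0.025319,
    0.025327,
    0.025327,
    0.025342,
    0.025350,
    0.025372,
    0.025388,
    0.025395,
    0.025395,
    0.025403,
    0.025426,
    0.025441,
    0.025448,
    0.025456,
    0.025456,
    0.025479,
    0.025486,
    0.025509,
    0.025532,
    0.025547,
    0.025555,
    0.025555,
    0.025562,
    0.025562,
    0.025600,
    0.025608,
    0.025608,
    0.025615,
    0.025623,
    0.025623,
    0.025661,
    0.025676,
    0.025684,
    0.025699,
    0.025699,
    0.025714,
    0.025714,
    0.025744,
    0.025744,
    0.025767,
    0.025767,
    0.025775,
    0.025805,
    0.025805,
    0.025813,
    0.025835,
    0.025843,
    0.025843,
    0.025858,
    0.025881,
    0.025919,
    0.025934,
    0.025980,
    0.025987,
    0.025987,
    0.025995,
    0.026010,
    0.026010,
    0.026033,
    0.026033,
    0.026048,
    0.026056,
    0.026063,
    0.026086,
    0.026116,
    0.026132,
    0.026139,
    0.026139,
    0.026223,
    0.026238,
    0.026238,
    0.026253,
    0.026268,
    0.026299,
    0.026299,
    0.026299,
    0.026299,
    0.026314,
    0.026337,
    0.026337,
    0.026344,
    0.026344,
    0.026367,
    0.026405,
    0.026405,
    0.026428,
    0.026443,
    0.026466,
    0.026466,
    0.026504,
    0.026511,
    0.026526,
    0.026541,
    0.026557,
    0.026564,
    0.026587,
    0.026587,
    0.026587,
    0.026617,
    0.026633,
    0.026648,
    0.026663,
    0.026671,
    0.026678,
    0.026686,
    0.026693,
    0.026716,
    0.026731,
    0.026746,
    0.026754,
    0.026754,
    0.026762,
    0.026762,
    0.026769,
    0.026769,
    0.026792,
    0.026830,
    0.026860,
    0.026860,
    0.026868,
    0.026906,
    0.026929,
    0.026944,
    0.026982,
    0.026997,
    0.026997,
    0.026997,
    0.027005,
    0.027027,
    0.027043,
    0.027058,
    0.027065,
    0.027073,
    0.027080,
    0.027096,
    0.027118,
    0.027118,
    0.027134,
    0.027164,
    0.027179,
    0.027217,
    0.027255,
    0.027263,
    0.027278,
    0.027278,
    0.027285,
    0.027293,
    0.027323,
    0.027392,
    0.027399,
    0.027445,
    0.027445,
    0.027468,
    0.027475,
    0.027475,
    0.027506,
    0.027513,
    0.027521,
    0.027521,
    0.027536,
    0.027536,
    0.027589,
    0.027619,
    0.027650,
    0.027650,
    0.027657,
    0.027657,
    0.027673,
    0.027680,
    0.027703,
    0.027726,
    0.027756,
    0.027786,
    0.027794,
    0.027794,
    0.027794,
    0.027802,
    0.027809,
    0.027809,
    0.027832,
    0.027847,
    0.027855,
    0.027870,
    0.027885,
    0.027885,
    0.027908,
    0.027969,
    0.027969,
    0.028022,
    0.028022,
    0.028037,
    0.028052,
    0.028052,
    0.028060,
    0.028060,
    0.028060,
    0.028083,
    0.028113,
    0.028151,
    0.028158,
    0.028174,
    0.028196,
    0.028204,
    0.028204,
    0.028219,
    0.028227,
    0.028234,
    0.028257,
    0.028280,
    0.028287,
    0.028356,
    0.028371,
    0.028379,
    0.028379,
    0.028386,
    0.028394,
    0.028394,
    0.028394,
    0.028401,
    0.028409,
    0.028424,
    0.028439,
    0.028462,
    0.028462,
    0.028515,
    0.028538,
    0.028553,
    0.028553,
    0.028614,
    0.028659,
    0.028713,
    0.028728,
    0.028735,
    0.028758,
    0.028758,
    0.028766,
    0.028773,
    0.028811,
    0.028880,
    0.028895,
    0.028902,
    0.028940,
    0.028940,
    0.028978,
    0.028978,
    0.028978,
    0.028986,
    0.028986,
    0.029009,
    0.029024,
    0.029039,
    0.029047,
    0.029107,
    0.029115,
    0.029123,
    0.029138,
    0.029145,
    0.029236,
    0.029244,
    0.029290,
    0.029343,
    0.029350,
    0.029373,
    0.029388,
    0.029396,
    0.029411,
    0.029434,
    0.029457,
    0.029494,
    0.029494,
    0.029540,
    0.029548,
    0.029608,
    0.029631,
    0.029639,
    0.029661,
    0.029684,
    0.029684,
    0.029699,
    0.029715,
    0.029745,
    0.029791,
    0.029791,
    0.029813,
    0.029844,
    0.029859,
    0.029874,
    0.029874,
    0.029995,
    0.030064,
    0.030071,
    0.030094,
    0.030125,
    0.030132,
    0.030140,
    0.030163,
    0.030163,
    0.030185,
    0.030193,
    0.030246,
    0.030276,
    0.030322,
    0.030375,
    0.030375,
    0.030383,
    0.030398,
    0.030398,
    0.030405,
    0.030436,
    0.030489,
    0.030497,
    0.030512,
    0.030519,
    0.030557,
    0.030565,
    0.030572,
    0.030618,
    0.030656,
    0.030717,
    0.030724,
    0.030739,
    0.030762,
    0.030777,
    0.030793,
    0.030831,
    0.030868,
    0.030922,
    0.030929,
    0.030937,
    0.030990,
    0.031028,
    0.031028,
    0.031043,
    0.031066,
    0.031081,
    0.031081,
    0.031119,
    0.031127,
    0.031165,
    0.031195,
    0.031210,
    0.031210,
    0.031225,
    0.031271,
    0.031423,
    0.031430,
    0.031445,
    0.031468,
    0.031514,
    0.031582,
    0.031590,
    0.031597,
    0.031628,
    0.031673,
    0.031719,
    0.031741,
    0.031764,
    0.031772,
    0.031833,
    0.031833,
    0.031840,
    0.031855,
    0.031916,
    0.031977,
    0.032000,
    0.032030,
    0.032121,
    0.032121,
    0.032121,
    0.032136,
    0.032144,
    0.032212,
    0.032220,
    0.032235,
    0.032303,
    0.032303,
    0.032349,
    0.032455,
    0.032478,
    0.032478,
    0.032493,
    0.032501,
    0.032516,
    0.032523,
    0.032539,
    0.032599,
    0.032645,
    0.032721,
    0.032766,
    0.032774,
    0.032804,
    0.032812,
    0.032888,
    0.032941,
    0.032956,
    0.032986,
    0.033024,
    0.033116,
    0.033161,
    0.033169,
    0.033229,
    0.033229,
    0.033252,
    0.033252,
    0.033305,
    0.033313,
    0.033495,
    0.033556,
    0.033571,
    0.033601,
    0.033654,
    0.033654,
    0.033708,
    0.033776,
    0.033852,
    0.033867,
    0.033867,
    0.033882,
    0.033951,
    0.033981,
    0.034034,
    0.034110,
    0.034125,
    0.034209,
    0.034247,
    0.034285,
    0.034353,
    0.034360,
    0.034406,
    0.034482,
    0.034505,
    0.034558,
    0.034634,
    0.034672,
    0.034937,
    0.034945,
    0.034960,
    0.034983,
    0.035006,
    0.035142,
    0.035211,
    0.035241,
    0.035241,
    0.035256,
    0.035302,
    0.035454,
    0.035530,
    0.035545,
    0.035605,
    0.035659,
    0.035772,
    0.035795,
    0.035795,
    0.035833,
    0.035833,
    0.035841,
    0.035932,
    0.036023,
    0.036061,
    0.036114,
    0.036144,
    0.036387,
    0.036410,
    0.036440,
    0.036494,
    0.036501,
    0.036585,
    0.036592,
    0.036668,
    0.036797,
    0.036866,
    0.036911,
    0.036972,
    0.037086,
    0.037124,
    0.037162,
    0.037367,
    0.037382,
    0.037594,
    0.037716,
    0.037951,
    0.038004,
    0.038073,
    0.038171,
    0.038247,
    0.038247,
    0.038255,
    0.038262,
    0.038346,
    0.038361,
    0.038361,
    0.038710,
    0.038756,
    0.038968,
    0.039173,
    0.039219,
    0.039242,
    0.039249,
    0.039477,
    0.040122,
    0.040304,
    0.040342,
    0.040730,
    0.040737,
    0.041079,
    0.041466,
    0.041519,
    0.041716,
    0.041868,
    0.042020,
    0.042073,
    0.042278,
    0.042438,
    0.043379,
    0.043493,
    0.043538,
    0.044229,
    0.044707,
    0.044890,
    0.045793,
    0.045823,
    0.058736,
]

DIP_NULL_N500 = [
    0.009376,
    0.009985,
    0.009992,
    0.010046,
    0.010099,
    0.010221,
    0.010381,
    0.010434,
    0.010617,
    0.010845,
    0.010876,
    0.010883,
    0.010914,
    0.010944,
    0.010959,
    0.011028,
    0.011043,
    0.011066,
    0.011142,
    0.011157,
    0.011165,
    0.011188,
    0.011188,
    0.011203,
    0.011294,
    0.011378,
    0.011393,
    0.011409,
    0.011431,
    0.011439,
    0.011447,
    0.011492,
    0.011492,
    0.011508,
    0.011546,
    0.011561,
    0.011561,
    0.011584,
    0.011591,
    0.011614,
    0.011637,
    0.011645,
    0.011660,
    0.011683,
    0.011789,
    0.011843,
    0.011850,
    0.011858,
    0.011911,
    0.011911,
    0.011934,
    0.011942,
    0.011949,
    0.011964,
    0.011964,
    0.011995,
    0.012002,
    0.012063,
    0.012101,
    0.012101,
    0.012117,
    0.012124,
    0.012147,
    0.012155,
    0.012155,
    0.012193,
    0.012193,
    0.012216,
    0.012223,
    0.012261,
    0.012337,
    0.012414,
    0.012429,
    0.012444,
    0.012444,
    0.012452,
    0.012459,
    0.012467,
    0.012475,
    0.012482,
    0.012505,
    0.012505,
    0.012513,
    0.012520,
    0.012520,
    0.012520,
    0.012543,
    0.012566,
    0.012573,
    0.012589,
    0.012596,
    0.012627,
    0.012634,
    0.012650,
    0.012650,
    0.012657,
    0.012665,
    0.012688,
    0.012695,
    0.012711,
    0.012718,
    0.012718,
    0.012741,
    0.012749,
    0.012756,
    0.012771,
    0.012771,
    0.012771,
    0.012787,
    0.012802,
    0.012802,
    0.012817,
    0.012825,
    0.012840,
    0.012855,
    0.012878,
    0.012886,
    0.012901,
    0.012909,
    0.012924,
    0.012954,
    0.012969,
    0.012977,
    0.013000,
    0.013000,
    0.013000,
    0.013007,
    0.013007,
    0.013023,
    0.013030,
    0.013053,
    0.013068,
    0.013068,
    0.013068,
    0.013084,
    0.013084,
    0.013084,
    0.013099,
    0.013099,
    0.013114,
    0.013114,
    0.013160,
    0.013175,
    0.013175,
    0.013183,
    0.013198,
    0.013198,
    0.013221,
    0.013236,
    0.013236,
    0.013259,
    0.013259,
    0.013266,
    0.013266,
    0.013282,
    0.013282,
    0.013289,
    0.013289,
    0.013304,
    0.013327,
    0.013335,
    0.013335,
    0.013335,
    0.013343,
    0.013350,
    0.013350,
    0.013358,
    0.013365,
    0.013381,
    0.013388,
    0.013411,
    0.013457,
    0.013464,
    0.013472,
    0.013480,
    0.013480,
    0.013487,
    0.013487,
    0.013495,
    0.013502,
    0.013510,
    0.013533,
    0.013548,
    0.013563,
    0.013586,
    0.013586,
    0.013594,
    0.013617,
    0.013632,
    0.013639,
    0.013639,
    0.013639,
    0.013678,
    0.013708,
    0.013716,
    0.013738,
    0.013738,
    0.013754,
    0.013761,
    0.013761,
    0.013761,
    0.013784,
    0.013792,
    0.013807,
    0.013815,
    0.013830,
    0.013830,
    0.013853,
    0.013868,
    0.013876,
    0.013883,
    0.013898,
    0.013921,
    0.013921,
    0.013929,
    0.013936,
    0.013936,
    0.013944,
    0.013959,
    0.013959,
    0.013982,
    0.013990,
    0.014013,
    0.014020,
    0.014028,
    0.014035,
    0.014043,
    0.014051,
    0.014058,
    0.014058,
    0.014081,
    0.014096,
    0.014119,
    0.014127,
    0.014134,
    0.014142,
    0.014150,
    0.014150,
    0.014172,
    0.014172,
    0.014172,
    0.014188,
    0.014195,
    0.014211,
    0.014211,
    0.014249,
    0.014264,
    0.014264,
    0.014271,
    0.014271,
    0.014294,
    0.014294,
    0.014294,
    0.014310,
    0.014332,
    0.014340,
    0.014348,
    0.014355,
    0.014363,
    0.014363,
    0.014370,
    0.014378,
    0.014378,
    0.014386,
    0.014393,
    0.014393,
    0.014393,
    0.014401,
    0.014454,
    0.014454,
    0.014469,
    0.014469,
    0.014485,
    0.014492,
    0.014515,
    0.014523,
    0.014523,
    0.014530,
    0.014538,
    0.014546,
    0.014553,
    0.014561,
    0.014561,
    0.014568,
    0.014568,
    0.014568,
    0.014576,
    0.014576,
    0.014576,
    0.014591,
    0.014599,
    0.014614,
    0.014629,
    0.014637,
    0.014645,
    0.014660,
    0.014667,
    0.014698,
    0.014698,
    0.014705,
    0.014713,
    0.014728,
    0.014728,
    0.014728,
    0.014736,
    0.014759,
    0.014774,
    0.014774,
    0.014782,
    0.014797,
    0.014797,
    0.014812,
    0.014820,
    0.014820,
    0.014827,
    0.014835,
    0.014850,
    0.014858,
    0.014873,
    0.014881,
    0.014881,
    0.014881,
    0.014903,
    0.014903,
    0.014949,
    0.014957,
    0.014957,
    0.014964,
    0.014995,
    0.015002,
    0.015010,
    0.015018,
    0.015018,
    0.015025,
    0.015033,
    0.015040,
    0.015063,
    0.015063,
    0.015071,
    0.015071,
    0.015094,
    0.015094,
    0.015109,
    0.015109,
    0.015117,
    0.015124,
    0.015139,
    0.015147,
    0.015155,
    0.015155,
    0.015155,
    0.015155,
    0.015162,
    0.015162,
    0.015178,
    0.015185,
    0.015193,
    0.015193,
    0.015208,
    0.015216,
    0.015231,
    0.015238,
    0.015238,
    0.015246,
    0.015246,
    0.015254,
    0.015254,
    0.015261,
    0.015269,
    0.015269,
    0.015277,
    0.015292,
    0.015292,
    0.015292,
    0.015307,
    0.015315,
    0.015315,
    0.015330,
    0.015345,
    0.015353,
    0.015353,
    0.015353,
    0.015360,
    0.015368,
    0.015368,
    0.015383,
    0.015383,
    0.015391,
    0.015398,
    0.015398,
    0.015398,
    0.015406,
    0.015406,
    0.015414,
    0.015421,
    0.015421,
    0.015429,
    0.015436,
    0.015444,
    0.015452,
    0.015459,
    0.015505,
    0.015513,
    0.015520,
    0.015528,
    0.015528,
    0.015528,
    0.015535,
    0.015535,
    0.015566,
    0.015566,
    0.015589,
    0.015589,
    0.015596,
    0.015596,
    0.015604,
    0.015604,
    0.015612,
    0.015612,
    0.015627,
    0.015642,
    0.015642,
    0.015657,
    0.015665,
    0.015665,
    0.015672,
    0.015680,
    0.015695,
    0.015695,
    0.015703,
    0.015711,
    0.015726,
    0.015733,
    0.015749,
    0.015771,
    0.015779,
    0.015787,
    0.015787,
    0.015787,
    0.015802,
    0.015809,
    0.015832,
    0.015832,
    0.015840,
    0.015840,
    0.015848,
    0.015855,
    0.015855,
    0.015870,
    0.015870,
    0.015878,
    0.015878,
    0.015886,
    0.015901,
    0.015924,
    0.015924,
    0.015954,
    0.015962,
    0.015977,
    0.015985,
    0.016023,
    0.016038,
    0.016046,
    0.016061,
    0.016076,
    0.016084,
    0.016084,
    0.016084,
    0.016091,
    0.016106,
    0.016114,
    0.016122,
    0.016129,
    0.016137,
    0.016145,
    0.016160,
    0.016183,
    0.016205,
    0.016213,
    0.016228,
    0.016243,
    0.016259,
    0.016259,
    0.016266,
    0.016274,
    0.016282,
    0.016282,
    0.016297,
    0.016304,
    0.016304,
    0.016312,
    0.016312,
    0.016312,
    0.016320,
    0.016327,
    0.016327,
    0.016342,
    0.016342,
    0.016373,
    0.016373,
    0.016373,
    0.016381,
    0.016388,
    0.016396,
    0.016419,
    0.016426,
    0.016426,
    0.016426,
    0.016449,
    0.016464,
    0.016480,
    0.016487,
    0.016487,
    0.016487,
    0.016487,
    0.016502,
    0.016502,
    0.016525,
    0.016533,
    0.016540,
    0.016548,
    0.016556,
    0.016594,
    0.016601,
    0.016601,
    0.016609,
    0.016617,
    0.016617,
    0.016632,
    0.016632,
    0.016639,
    0.016678,
    0.016678,
    0.016685,
    0.016700,
    0.016700,
    0.016708,
    0.016716,
    0.016738,
    0.016738,
    0.016754,
    0.016761,
    0.016776,
    0.016776,
    0.016776,
    0.016784,
    0.016784,
    0.016792,
    0.016807,
    0.016807,
    0.016815,
    0.016822,
    0.016822,
    0.016853,
    0.016853,
    0.016860,
    0.016860,
    0.016868,
    0.016868,
    0.016875,
    0.016875,
    0.016883,
    0.016891,
    0.016891,
    0.016898,
    0.016906,
    0.016914,
    0.016914,
    0.016921,
    0.016967,
    0.016974,
    0.016990,
    0.016990,
    0.016997,
    0.016997,
    0.017005,
    0.017020,
    0.017035,
    0.017066,
    0.017081,
    0.017104,
    0.017104,
    0.017127,
    0.017142,
    0.017188,
    0.017195,
    0.017210,
    0.017218,
    0.017218,
    0.017241,
    0.017256,
    0.017256,
    0.017256,
    0.017256,
    0.017264,
    0.017271,
    0.017271,
    0.017271,
    0.017287,
    0.017309,
    0.017309,
    0.017325,
    0.017332,
    0.017348,
    0.017355,
    0.017363,
    0.017370,
    0.017370,
    0.017386,
    0.017401,
    0.017408,
    0.017416,
    0.017447,
    0.017469,
    0.017492,
    0.017492,
    0.017500,
    0.017515,
    0.017546,
    0.017561,
    0.017576,
    0.017584,
    0.017599,
    0.017599,
    0.017599,
    0.017606,
    0.017629,
    0.017629,
    0.017660,
    0.017667,
    0.017675,
    0.017683,
    0.017698,
    0.017728,
    0.017728,
    0.017736,
    0.017743,
    0.017751,
    0.017751,
    0.017759,
    0.017766,
    0.017774,
    0.017797,
    0.017804,
    0.017842,
    0.017850,
    0.017865,
    0.017865,
    0.017888,
    0.017888,
    0.017888,
    0.017919,
    0.017934,
    0.017949,
    0.017957,
    0.017964,
    0.017964,
    0.017964,
    0.017964,
    0.017972,
    0.017987,
    0.018025,
    0.018025,
    0.018033,
    0.018033,
    0.018040,
    0.018048,
    0.018048,
    0.018079,
    0.018094,
    0.018094,
    0.018124,
    0.018139,
    0.018147,
    0.018155,
    0.018162,
    0.018170,
    0.018177,
    0.018200,
    0.018208,
    0.018216,
    0.018223,
    0.018238,
    0.018261,
    0.018269,
    0.018284,
    0.018292,
    0.018322,
    0.018368,
    0.018375,
    0.018383,
    0.018398,
    0.018406,
    0.018414,
    0.018414,
    0.018429,
    0.018429,
    0.018436,
    0.018444,
    0.018467,
    0.018474,
    0.018482,
    0.018543,
    0.018551,
    0.018573,
    0.018581,
    0.018589,
    0.018596,
    0.018596,
    0.018596,
    0.018596,
    0.018619,
    0.018634,
    0.018642,
    0.018650,
    0.018703,
    0.018703,
    0.018710,
    0.018726,
    0.018733,
    0.018733,
    0.018756,
    0.018771,
    0.018771,
    0.018787,
    0.018802,
    0.018825,
    0.018832,
    0.018832,
    0.018832,
    0.018878,
    0.018878,
    0.018886,
    0.018931,
    0.018931,
    0.018931,
    0.018947,
    0.018947,
    0.018947,
    0.018954,
    0.018977,
    0.018985,
    0.018992,
    0.019007,
    0.019007,
    0.019007,
    0.019023,
    0.019023,
    0.019023,
    0.019023,
    0.019030,
    0.019030,
    0.019038,
    0.019038,
    0.019053,
    0.019061,
    0.019068,
    0.019076,
    0.019084,
    0.019099,
    0.019114,
    0.019122,
    0.019137,
    0.019183,
    0.019183,
    0.019190,
    0.019198,
    0.019213,
    0.019243,
    0.019243,
    0.019251,
    0.019251,
    0.019266,
    0.019266,
    0.019289,
    0.019297,
    0.019297,
    0.019304,
    0.019327,
    0.019327,
    0.019342,
    0.019358,
    0.019373,
    0.019388,
    0.019396,
    0.019403,
    0.019419,
    0.019419,
    0.019426,
    0.019457,
    0.019487,
    0.019525,
    0.019525,
    0.019556,
    0.019586,
    0.019601,
    0.019609,
    0.019617,
    0.019647,
    0.019685,
    0.019693,
    0.019716,
    0.019761,
    0.019776,
    0.019792,
    0.019822,
    0.019822,
    0.019837,
    0.019883,
    0.019921,
    0.019929,
    0.019959,
    0.019967,
    0.019967,
    0.020005,
    0.020043,
    0.020066,
    0.020096,
    0.020127,
    0.020188,
    0.020195,
    0.020210,
    0.020210,
    0.020218,
    0.020233,
    0.020241,
    0.020256,
    0.020340,
    0.020348,
    0.020355,
    0.020355,
    0.020363,
    0.020363,
    0.020401,
    0.020424,
    0.020447,
    0.020530,
    0.020568,
    0.020591,
    0.020614,
    0.020622,
    0.020644,
    0.020644,
    0.020660,
    0.020698,
    0.020705,
    0.020705,
    0.020728,
    0.020751,
    0.020766,
    0.020789,
    0.020804,
    0.020820,
    0.020820,
    0.020820,
    0.020881,
    0.020888,
    0.020888,
    0.020888,
    0.020926,
    0.020941,
    0.020941,
    0.020949,
    0.020972,
    0.020979,
    0.020979,
    0.020995,
    0.021018,
    0.021048,
    0.021063,
    0.021063,
    0.021124,
    0.021139,
    0.021147,
    0.021185,
    0.021185,
    0.021193,
    0.021254,
    0.021254,
    0.021299,
    0.021330,
    0.021391,
    0.021452,
    0.021474,
    0.021543,
    0.021558,
    0.021596,
    0.021619,
    0.021688,
    0.021703,
    0.021749,
    0.021756,
    0.021771,
    0.021787,
    0.021787,
    0.021787,
    0.021832,
    0.021863,
    0.021863,
    0.021939,
    0.022023,
    0.022122,
    0.022144,
    0.022167,
    0.022183,
    0.022251,
    0.022289,
    0.022365,
    0.022365,
    0.022403,
    0.022472,
    0.022472,
    0.022571,
    0.022586,
    0.022601,
    0.022670,
    0.022677,
    0.022716,
    0.022731,
    0.022738,
    0.022860,
    0.022952,
    0.022997,
    0.023043,
    0.023058,
    0.023119,
    0.023157,
    0.023195,
    0.023218,
    0.023241,
    0.023309,
    0.023401,
    0.023431,
    0.023507,
    0.023530,
    0.023599,
    0.023652,
    0.023660,
    0.023781,
    0.023850,
    0.023850,
    0.023873,
    0.023880,
    0.023979,
    0.023995,
    0.024025,
    0.024086,
    0.024193,
    0.024200,
    0.024223,
    0.024246,
    0.024337,
    0.024337,
    0.024353,
    0.024421,
    0.024505,
    0.024543,
    0.024558,
    0.024733,
    0.024748,
    0.024756,
    0.024809,
    0.024817,
    0.024931,
    0.024992,
    0.025099,
    0.025380,
    0.025426,
    0.025548,
    0.025548,
    0.025662,
    0.025677,
    0.025906,
    0.025959,
    0.025997,
    0.026104,
    0.026134,
    0.026203,
    0.026226,
    0.026264,
    0.026287,
    0.026309,
    0.026462,
    0.026682,
    0.027307,
    0.027535,
    0.027573,
    0.027634,
    0.027771,
    0.027886,
    0.028076,
    0.028563,
    0.028609,
    0.028639,
    0.028814,
    0.029622,
    0.029644,
    0.029705,
    0.031114,
]

DIP_NULL_N1000 = [
    0.006658,
    0.006994,
    0.006994,
    0.007108,
    0.007352,
    0.007527,
    0.007558,
    0.007687,
    0.007710,
    0.007764,
    0.007832,
    0.007924,
    0.007924,
    0.008000,
    0.008015,
    0.008038,
    0.008167,
    0.008190,
    0.008206,
    0.008228,
    0.008228,
    0.008297,
    0.008328,
    0.008366,
    0.008381,
    0.008404,
    0.008419,
    0.008457,
    0.008457,
    0.008457,
    0.008472,
    0.008495,
    0.008503,
    0.008510,
    0.008533,
    0.008533,
    0.008549,
    0.008549,
    0.008564,
    0.008571,
    0.008579,
    0.008594,
    0.008594,
    0.008617,
    0.008632,
    0.008632,
    0.008640,
    0.008655,
    0.008655,
    0.008655,
    0.008678,
    0.008678,
    0.008686,
    0.008686,
    0.008686,
    0.008693,
    0.008732,
    0.008739,
    0.008754,
    0.008754,
    0.008770,
    0.008770,
    0.008777,
    0.008785,
    0.008800,
    0.008808,
    0.008808,
    0.008823,
    0.008846,
    0.008846,
    0.008853,
    0.008861,
    0.008861,
    0.008869,
    0.008876,
    0.008892,
    0.008914,
    0.008922,
    0.008930,
    0.008930,
    0.008937,
    0.008937,
    0.008945,
    0.008953,
    0.008953,
    0.008998,
    0.009006,
    0.009006,
    0.009029,
    0.009036,
    0.009067,
    0.009082,
    0.009105,
    0.009105,
    0.009128,
    0.009135,
    0.009143,
    0.009143,
    0.009151,
    0.009151,
    0.009158,
    0.009166,
    0.009166,
    0.009189,
    0.009189,
    0.009219,
    0.009227,
    0.009235,
    0.009242,
    0.009250,
    0.009250,
    0.009273,
    0.009273,
    0.009288,
    0.009296,
    0.009296,
    0.009296,
    0.009318,
    0.009318,
    0.009334,
    0.009341,
    0.009364,
    0.009364,
    0.009372,
    0.009379,
    0.009379,
    0.009387,
    0.009395,
    0.009402,
    0.009410,
    0.009417,
    0.009433,
    0.009433,
    0.009440,
    0.009440,
    0.009448,
    0.009494,
    0.009494,
    0.009509,
    0.009509,
    0.009509,
    0.009517,
    0.009517,
    0.009517,
    0.009517,
    0.009532,
    0.009532,
    0.009547,
    0.009555,
    0.009570,
    0.009578,
    0.009585,
    0.009585,
    0.009600,
    0.009608,
    0.009608,
    0.009608,
    0.009623,
    0.009623,
    0.009631,
    0.009638,
    0.009638,
    0.009638,
    0.009669,
    0.009669,
    0.009684,
    0.009699,
    0.009699,
    0.009715,
    0.009730,
    0.009738,
    0.009745,
    0.009745,
    0.009753,
    0.009753,
    0.009760,
    0.009791,
    0.009791,
    0.009791,
    0.009791,
    0.009799,
    0.009799,
    0.009806,
    0.009806,
    0.009821,
    0.009837,
    0.009890,
    0.009890,
    0.009890,
    0.009898,
    0.009928,
    0.009928,
    0.009928,
    0.009943,
    0.009951,
    0.009951,
    0.009959,
    0.009959,
    0.009981,
    0.009997,
    0.009997,
    0.010012,
    0.010012,
    0.010012,
    0.010012,
    0.010020,
    0.010027,
    0.010035,
    0.010058,
    0.010065,
    0.010081,
    0.010088,
    0.010088,
    0.010096,
    0.010103,
    0.010103,
    0.010119,
    0.010126,
    0.010126,
    0.010134,
    0.010142,
    0.010142,
    0.010142,
    0.010149,
    0.010157,
    0.010157,
    0.010164,
    0.010180,
    0.010180,
    0.010180,
    0.010187,
    0.010195,
    0.010210,
    0.010210,
    0.010218,
    0.010225,
    0.010241,
    0.010241,
    0.010256,
    0.010271,
    0.010271,
    0.010279,
    0.010286,
    0.010294,
    0.010302,
    0.010309,
    0.010332,
    0.010332,
    0.010340,
    0.010340,
    0.010347,
    0.010347,
    0.010355,
    0.010370,
    0.010370,
    0.010378,
    0.010393,
    0.010408,
    0.010416,
    0.010416,
    0.010416,
    0.010431,
    0.010439,
    0.010439,
    0.010446,
    0.010446,
    0.010446,
    0.010454,
    0.010454,
    0.010454,
    0.010462,
    0.010485,
    0.010500,
    0.010515,
    0.010515,
    0.010523,
    0.010530,
    0.010538,
    0.010545,
    0.010561,
    0.010561,
    0.010561,
    0.010568,
    0.010568,
    0.010576,
    0.010584,
    0.010591,
    0.010599,
    0.010599,
    0.010606,
    0.010622,
    0.010637,
    0.010645,
    0.010645,
    0.010645,
    0.010652,
    0.010652,
    0.010660,
    0.010660,
    0.010660,
    0.010660,
    0.010667,
    0.010667,
    0.010675,
    0.010698,
    0.010698,
    0.010706,
    0.010706,
    0.010728,
    0.010736,
    0.010736,
    0.010744,
    0.010751,
    0.010759,
    0.010767,
    0.010767,
    0.010767,
    0.010774,
    0.010782,
    0.010789,
    0.010805,
    0.010835,
    0.010835,
    0.010843,
    0.010850,
    0.010850,
    0.010850,
    0.010858,
    0.010858,
    0.010866,
    0.010866,
    0.010866,
    0.010896,
    0.010896,
    0.010896,
    0.010911,
    0.010919,
    0.010927,
    0.010934,
    0.010942,
    0.010942,
    0.010949,
    0.010949,
    0.010949,
    0.010957,
    0.010957,
    0.010965,
    0.010965,
    0.010972,
    0.010988,
    0.010995,
    0.011003,
    0.011003,
    0.011010,
    0.011010,
    0.011026,
    0.011033,
    0.011033,
    0.011049,
    0.011056,
    0.011056,
    0.011064,
    0.011064,
    0.011064,
    0.011071,
    0.011071,
    0.011087,
    0.011094,
    0.011094,
    0.011102,
    0.011132,
    0.011140,
    0.011148,
    0.011155,
    0.011163,
    0.011163,
    0.011163,
    0.011170,
    0.011170,
    0.011186,
    0.011193,
    0.011193,
    0.011201,
    0.011201,
    0.011209,
    0.011216,
    0.011216,
    0.011216,
    0.011224,
    0.011224,
    0.011239,
    0.011239,
    0.011247,
    0.011247,
    0.011262,
    0.011277,
    0.011292,
    0.011292,
    0.011292,
    0.011292,
    0.011308,
    0.011315,
    0.011338,
    0.011338,
    0.011346,
    0.011353,
    0.011353,
    0.011361,
    0.011369,
    0.011376,
    0.011376,
    0.011376,
    0.011384,
    0.011392,
    0.011407,
    0.011414,
    0.011414,
    0.011422,
    0.011422,
    0.011430,
    0.011430,
    0.011430,
    0.011437,
    0.011445,
    0.011445,
    0.011460,
    0.011460,
    0.011468,
    0.011475,
    0.011475,
    0.011483,
    0.011483,
    0.011483,
    0.011483,
    0.011498,
    0.011498,
    0.011506,
    0.011559,
    0.011559,
    0.011559,
    0.011559,
    0.011567,
    0.011574,
    0.011574,
    0.011590,
    0.011590,
    0.011597,
    0.011613,
    0.011620,
    0.011628,
    0.011635,
    0.011635,
    0.011635,
    0.011635,
    0.011635,
    0.011643,
    0.011658,
    0.011658,
    0.011658,
    0.011666,
    0.011689,
    0.011704,
    0.011727,
    0.011734,
    0.011742,
    0.011742,
    0.011750,
    0.011750,
    0.011757,
    0.011765,
    0.011773,
    0.011780,
    0.011780,
    0.011788,
    0.011788,
    0.011795,
    0.011803,
    0.011803,
    0.011803,
    0.011818,
    0.011849,
    0.011856,
    0.011856,
    0.011856,
    0.011856,
    0.011864,
    0.011864,
    0.011887,
    0.011887,
    0.011887,
    0.011887,
    0.011895,
    0.011895,
    0.011917,
    0.011925,
    0.011925,
    0.011940,
    0.011948,
    0.011963,
    0.011963,
    0.011963,
    0.011971,
    0.011986,
    0.012001,
    0.012016,
    0.012024,
    0.012039,
    0.012047,
    0.012047,
    0.012055,
    0.012055,
    0.012062,
    0.012062,
    0.012062,
    0.012070,
    0.012070,
    0.012070,
    0.012070,
    0.012070,
    0.012085,
    0.012085,
    0.012093,
    0.012093,
    0.012108,
    0.012108,
    0.012108,
    0.012116,
    0.012116,
    0.012123,
    0.012131,
    0.012131,
    0.012138,
    0.012146,
    0.012161,
    0.012169,
    0.012177,
    0.012184,
    0.012184,
    0.012192,
    0.012192,
    0.012199,
    0.012207,
    0.012215,
    0.012215,
    0.012215,
    0.012222,
    0.012230,
    0.012230,
    0.012238,
    0.012253,
    0.012260,
    0.012268,
    0.012276,
    0.012276,
    0.012298,
    0.012298,
    0.012298,
    0.012298,
    0.012321,
    0.012329,
    0.012337,
    0.012344,
    0.012359,
    0.012359,
    0.012375,
    0.012382,
    0.012382,
    0.012382,
    0.012398,
    0.012413,
    0.012420,
    0.012436,
    0.012443,
    0.012451,
    0.012466,
    0.012466,
    0.012466,
    0.012466,
    0.012474,
    0.012474,
    0.012481,
    0.012481,
    0.012481,
    0.012489,
    0.012512,
    0.012520,
    0.012520,
    0.012527,
    0.012535,
    0.012550,
    0.012550,
    0.012558,
    0.012588,
    0.012596,
    0.012619,
    0.012626,
    0.012634,
    0.012634,
    0.012657,
    0.012664,
    0.012664,
    0.012664,
    0.012672,
    0.012695,
    0.012710,
    0.012725,
    0.012725,
    0.012725,
    0.012741,
    0.012741,
    0.012748,
    0.012748,
    0.012756,
    0.012763,
    0.012771,
    0.012786,
    0.012786,
    0.012786,
    0.012794,
    0.012809,
    0.012824,
    0.012832,
    0.012832,
    0.012840,
    0.012847,
    0.012847,
    0.012870,
    0.012870,
    0.012870,
    0.012870,
    0.012870,
    0.012878,
    0.012885,
    0.012908,
    0.012916,
    0.012916,
    0.012923,
    0.012923,
    0.012946,
    0.012969,
    0.012969,
    0.012984,
    0.012984,
    0.012992,
    0.013000,
    0.013007,
    0.013015,
    0.013030,
    0.013030,
    0.013038,
    0.013053,
    0.013053,
    0.013061,
    0.013068,
    0.013076,
    0.013076,
    0.013091,
    0.013091,
    0.013091,
    0.013099,
    0.013106,
    0.013114,
    0.013114,
    0.013129,
    0.013137,
    0.013145,
    0.013167,
    0.013183,
    0.013190,
    0.013190,
    0.013198,
    0.013205,
    0.013236,
    0.013251,
    0.013259,
    0.013259,
    0.013282,
    0.013297,
    0.013312,
    0.013312,
    0.013327,
    0.013343,
    0.013373,
    0.013404,
    0.013419,
    0.013427,
    0.013449,
    0.013480,
    0.013503,
    0.013510,
    0.013518,
    0.013518,
    0.013518,
    0.013526,
    0.013541,
    0.013541,
    0.013594,
    0.013594,
    0.013602,
    0.013602,
    0.013602,
    0.013602,
    0.013625,
    0.013632,
    0.013632,
    0.013655,
    0.013663,
    0.013686,
    0.013693,
    0.013701,
    0.013716,
    0.013716,
    0.013716,
    0.013716,
    0.013724,
    0.013739,
    0.013754,
    0.013754,
    0.013792,
    0.013800,
    0.013800,
    0.013830,
    0.013838,
    0.013838,
    0.013861,
    0.013869,
    0.013884,
    0.013884,
    0.013884,
    0.013899,
    0.013907,
    0.013922,
    0.013930,
    0.013930,
    0.013937,
    0.013960,
    0.013960,
    0.013960,
    0.013968,
    0.013975,
    0.013975,
    0.013983,
    0.013991,
    0.013991,
    0.013998,
    0.014036,
    0.014036,
    0.014051,
    0.014051,
    0.014059,
    0.014090,
    0.014090,
    0.014097,
    0.014097,
    0.014158,
    0.014158,
    0.014166,
    0.014173,
    0.014189,
    0.014204,
    0.014204,
    0.014204,
    0.014204,
    0.014219,
    0.014257,
    0.014280,
    0.014288,
    0.014303,
    0.014311,
    0.014334,
    0.014349,
    0.014372,
    0.014394,
    0.014394,
    0.014394,
    0.014402,
    0.014410,
    0.014410,
    0.014417,
    0.014417,
    0.014425,
    0.014440,
    0.014448,
    0.014455,
    0.014455,
    0.014478,
    0.014486,
    0.014494,
    0.014524,
    0.014539,
    0.014539,
    0.014539,
    0.014547,
    0.014555,
    0.014562,
    0.014562,
    0.014562,
    0.014570,
    0.014570,
    0.014570,
    0.014577,
    0.014593,
    0.014600,
    0.014638,
    0.014646,
    0.014692,
    0.014692,
    0.014745,
    0.014745,
    0.014753,
    0.014768,
    0.014783,
    0.014791,
    0.014821,
    0.014829,
    0.014837,
    0.014844,
    0.014875,
    0.014890,
    0.014890,
    0.014905,
    0.014928,
    0.014936,
    0.014943,
    0.014997,
    0.015019,
    0.015035,
    0.015058,
    0.015065,
    0.015080,
    0.015134,
    0.015141,
    0.015149,
    0.015187,
    0.015187,
    0.015187,
    0.015195,
    0.015210,
    0.015225,
    0.015225,
    0.015286,
    0.015286,
    0.015301,
    0.015301,
    0.015332,
    0.015332,
    0.015385,
    0.015416,
    0.015423,
    0.015439,
    0.015446,
    0.015469,
    0.015484,
    0.015484,
    0.015500,
    0.015507,
    0.015515,
    0.015545,
    0.015561,
    0.015561,
    0.015583,
    0.015614,
    0.015629,
    0.015667,
    0.015683,
    0.015705,
    0.015728,
    0.015782,
    0.015789,
    0.015820,
    0.015835,
    0.015850,
    0.015858,
    0.015873,
    0.015881,
    0.015942,
    0.015949,
    0.015972,
    0.015980,
    0.015980,
    0.015987,
    0.015987,
    0.016010,
    0.016026,
    0.016048,
    0.016064,
    0.016094,
    0.016140,
    0.016140,
    0.016155,
    0.016186,
    0.016216,
    0.016239,
    0.016239,
    0.016247,
    0.016285,
    0.016315,
    0.016330,
    0.016346,
    0.016353,
    0.016376,
    0.016376,
    0.016452,
    0.016475,
    0.016513,
    0.016529,
    0.016536,
    0.016551,
    0.016590,
    0.016711,
    0.016719,
    0.016719,
    0.016833,
    0.016879,
    0.016902,
    0.016917,
    0.016925,
    0.016933,
    0.016955,
    0.016955,
    0.016971,
    0.016978,
    0.016986,
    0.017009,
    0.017016,
    0.017108,
    0.017123,
    0.017138,
    0.017184,
    0.017237,
    0.017237,
    0.017253,
    0.017253,
    0.017268,
    0.017276,
    0.017336,
    0.017352,
    0.017375,
    0.017382,
    0.017390,
    0.017428,
    0.017458,
    0.017481,
    0.017489,
    0.017497,
    0.017504,
    0.017519,
    0.017519,
    0.017550,
    0.017596,
    0.017657,
    0.017664,
    0.017718,
    0.017756,
    0.017794,
    0.017824,
    0.017900,
    0.017923,
    0.018000,
    0.018182,
    0.018182,
    0.018198,
    0.018213,
    0.018228,
    0.018388,
    0.018465,
    0.018472,
    0.018518,
    0.018525,
    0.018586,
    0.018609,
    0.018678,
    0.018724,
    0.018762,
    0.018800,
    0.018807,
    0.018884,
    0.018884,
    0.019097,
    0.019112,
    0.019128,
    0.019158,
    0.019196,
    0.019196,
    0.019326,
    0.019631,
    0.019928,
    0.019989,
    0.020141,
    0.020263,
    0.020431,
    0.020896,
    0.020949,
    0.021185,
    0.021506,
    0.021818,
    0.022580,
    0.022641,
    0.027054,
]
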
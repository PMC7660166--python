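aid,abbreviation,criterion,auc,se,sp,acc,bac,mcc
720516,ATAD5_ind,40,0.840,0.750,0.843,0.840,0.796,0.272
720516,ATAD5_ind,1,0.845,0.744,0.847,0.839,0.795,0.395
720552,p53_ago,40,0.899,0.824,0.830,0.830,0.827,0.356
720552,p53_ago,1,0.845,0.804,0.793,0.794,0.799,0.458
720637,MMP_disr,40,0.919,0.845,0.846,0.846,0.845,0.501
720637,MMP_disr,1,0.795,0.698,0.788,0.758,0.743,0.475
720719,GR_ago,40,0.783,0.600,0.931,0.923,0.766,0.300
720719,GR_ago,1,0.841,0.754,0.807,0.800,0.780,0.416
720725,GR_ant,40,0.808,0.577,0.905,0.888,0.741,0.328
720725,GR_ant,1,0.827,0.801,0.721,0.743,0.761,0.471
743053,Arlbd_ago,40,0.878,0.765,0.947,0.941,0.856,0.481
743053,Arlbd_ago,1,0.766,0.582,0.843,0.806,0.712,0.357
743054,ARfull_ant,40,0.774,0.750,0.681,0.683,0.716,0.169
743054,ARfull_ant,1,0.833,0.841,0.700,0.734,0.770,0.468
743063,Arlbd_ant,40,0.844,0.786,0.791,0.790,0.788,0.338
743063,Arlbd_ant,1,0.833,0.805,0.724,0.745,0.765,0.469
743067,TR_ant,40,0.783,0.511,0.924,0.906,0.718,0.306
743067,TR_ant,1,0.829,0.740,0.825,0.796,0.782,0.555
743077,ERlbd_ago,40,0.782,0.536,0.961,0.938,0.748,0.457
743077,ERlbd_ago,1,0.735,0.600,0.843,0.812,0.722,0.362
743078,ERlbd_ant,40,0.810,0.815,0.684,0.691,0.750,0.237
743078,ERlbd_ant,1,0.805,0.696,0.789,0.767,0.743,0.444
743091,ERfull_ant,40,0.826,0.872,0.699,0.705,0.785,0.235
743091,ERfull_ant,1,0.862,0.730,0.870,0.842,0.800,0.555
743122,AhR_ago,40,0.888,0.713,0.907,0.887,0.810,0.513
743122,AhR_ago,1,0.749,0.728,0.695,0.702,0.711,0.359
743139,Arom_ant,40,0.801,0.892,0.598,0.608,0.745,0.186
743139,Arom_ant,1,0.807,0.825,0.661,0.704,0.743,0.429
743140,PPARg_ago,40,0.813,0.750,0.823,0.821,0.786,0.238
743140,PPARg_ago,1,0.832,0.735,0.819,0.805,0.777,0.457
743199,PPARg_ant,40,0.829,0.786,0.798,0.798,0.792,0.290
743199,PPARg_ant,1,0.810,0.824,0.645,0.682,0.734,0.383
743219,ARE_ago,40,0.785,0.794,0.652,0.672,0.723,0.317
743219,ARE_ago,1,0.795,0.770,0.715,0.733,0.742,0.461
743226,PPARd_ant,40,0.681,0.600,0.885,0.884,0.743,0.111
743226,PPARd_ant,1,0.811,0.764,0.749,0.751,0.756,0.374
743227,PPARd_ago,40,0.812,0.615,0.954,0.949,0.785,0.296
743227,PPARd_ago,1,0.796,0.705,0.790,0.780,0.747,0.356
743228,HSR_act,40,0.788,0.576,0.922,0.910,0.749,0.315
743228,HSR_act,1,0.790,0.667,0.808,0.789,0.737,0.370
743239,FXR_ago,40,0.775,0.727,0.836,0.835,0.782,0.163
743239,FXR_ago,1,0.817,0.689,0.834,0.825,0.762,0.325
743240,FXR_ant,40,0.757,0.933,0.565,0.577,0.749,0.178
743240,FXR_ant,1,0.843,0.788,0.799,0.798,0.794,0.481
743241,VDR_ago,40,,,,,,
743241,VDR_ago,1,0.826,0.769,0.727,0.730,0.748,0.297
743242,VDR_ant,40,0.716,1.000,0.399,0.403,0.699,0.066
743242,VDR_ant,1,0.701,0.630,0.689,0.678,0.660,0.258
1159518,NFkB_ago,40,0.780,0.667,0.846,0.846,0.756,0.081
1159518,NFkB_ago,1,0.871,0.692,0.912,0.900,0.802,0.427
1159519,ERsr_ago,40,0.638,0.857,0.441,0.445,0.649,0.052
1159519,ERsr_ago,1,0.801,0.655,0.833,0.816,0.744,0.349
1159523,ROR_ant,40,0.828,0.789,0.764,0.766,0.777,0.323
1159523,ROR_ant,1,0.695,0.523,0.819,0.703,0.671,0.359
1159528,AP1_ago,40,0.777,0.553,0.877,0.851,0.715,0.319
1159528,AP1_ago,1,0.799,0.765,0.722,0.729,0.743,0.372
1159531,RXR_ago,40,0.532,0.235,0.964,0.951,0.600,0.135
1159531,RXR_ago,1,0.725,0.527,0.841,0.756,0.684,0.374
1159555,RAR_ant,40,0.831,0.800,0.742,0.746,0.771,0.308
1159555,RAR_ant,1,0.683,0.740,0.511,0.601,0.626,0.249
1224892,CAR_ago,40,0.889,0.826,0.808,0.810,0.817,0.455
1224892,CAR_ago,1,0.847,0.684,0.889,0.845,0.787,0.556
1224893,CAR_ant,40,0.809,0.652,0.880,0.874,0.766,0.239
1224893,CAR_ant,1,0.793,0.700,0.768,0.746,0.734,0.448
1224894,HIF1_ago,40,0.556,0.250,1.000,0.997,0.625,0.499
1224894,HIF1_ago,1,0.854,0.769,0.829,0.824,0.799,0.395
1224895,TSHR_ago,40,0.872,0.750,0.880,0.874,0.815,0.355
1224895,TSHR_ago,1,0.838,0.692,0.831,0.816,0.762,0.389
1224896,H2AX_ago,40,0.834,0.696,0.892,0.880,0.794,0.394
1224896,H2AX_ago,1,0.779,0.605,0.842,0.814,0.724,0.354
1259247,Arfulls_ant,40,0.856,0.857,0.733,0.747,0.795,0.401
1259247,Arfulls_ant,1,0.824,0.788,0.767,0.774,0.778,0.534
1259248,Erfulls_ant,40,0.835,0.850,0.702,0.711,0.776,0.283
1259248,Erfulls_ant,1,0.793,0.668,0.798,0.770,0.733,0.416
1259387,ARant_ago,40,0.852,0.727,0.946,0.939,0.837,0.460
1259387,ARant_ago,1,0.712,0.494,0.872,0.841,0.683,0.275
1259388,HDAC_ant,40,0.897,0.783,0.888,0.883,0.835,0.407
1259388,HDAC_ant,1,0.868,0.768,0.879,0.871,0.824,0.447
1259390,Shh_ago,40,0.571,1.000,0.219,0.223,0.609,0.042
1259390,Shh_ago,1,0.724,0.609,0.913,0.905,0.761,0.266
1259391,ERaant_ago,40,0.934,0.850,0.959,0.956,0.904,0.493
1259391,ERaant_ago,1,0.782,0.551,0.898,0.880,0.725,0.299
1259392,Shh_ant,40,0.829,0.809,0.718,0.731,0.764,0.379
1259392,Shh_ant,1,0.758,0.642,0.745,0.705,0.693,0.383
1259393,TSHR_agoant,40,0.834,0.750,0.875,0.874,0.812,0.120
1259393,TSHR_agoant,1,0.669,0.727,0.681,0.682,0.704,0.093
1259394,ERb_ago,40,0.980,0.923,0.973,0.972,0.948,0.531
1259394,ERb_ago,1,0.729,0.444,0.937,0.900,0.691,0.348
1259395,TSHR_ant,40,0.865,0.933,0.715,0.721,0.824,0.244
1259395,TSHR_ant,1,0.850,0.800,0.807,0.807,0.804,0.381
1259396,Erb_ant,40,0.825,0.677,0.863,0.851,0.770,0.352
1259396,Erb_ant,1,0.798,0.743,0.763,0.758,0.753,0.462
1259401,ERRPGC_ant,40,0.843,0.698,0.843,0.837,0.770,0.290
1259401,ERRPGC_ant,1,0.751,0.595,0.793,0.723,0.694,0.390
1259402,ERRPGC_ago,40,0.840,0.650,0.937,0.925,0.794,0.415
1259402,ERRPGC_ago,1,0.805,0.734,0.777,0.768,0.756,0.444
1259403,ERR_ant,40,0.812,0.653,0.856,0.835,0.755,0.392
1259403,ERR_ant,1,0.819,0.696,0.826,0.786,0.761,0.510
1259404,ERR_ago,40,0.884,0.880,0.814,0.816,0.847,0.274
1259404,ERR_ago,1,0.803,0.680,0.820,0.777,0.750,0.491
1347030,TRHR_ago,40,0.748,0.833,0.637,0.638,0.735,0.077
1347030,TRHR_ago,1,0.751,0.593,0.853,0.846,0.723,0.201
1347031,PR_ant,40,0.892,0.880,0.794,0.804,0.837,0.473
1347031,PR_ant,1,0.831,0.757,0.821,0.802,0.789,0.550
1347032,TGFb_ant,40,0.809,0.750,0.765,0.764,0.757,0.273
1347032,TGFb_ant,1,0.860,0.780,0.824,0.817,0.802,0.493
1347033,PXR_ago,40,0.851,0.759,0.817,0.805,0.788,0.517
1347033,PXR_ago,1,0.838,0.745,0.817,0.790,0.781,0.556
1347034,CaspH_ind,40,0.870,0.791,0.852,0.849,0.821,0.348
1347034,CaspH_ind,1,0.858,0.773,0.856,0.848,0.814,0.452
1347035,TGFb_ago,40,0.968,1.000,0.938,0.938,0.969,0.174
1347035,TGFb_ago,1,0.900,0.818,0.937,0.936,0.878,0.311
1347036,PR_ago,40,0.943,0.833,0.989,0.986,0.911,0.701
1347036,PR_ago,1,0.799,0.537,0.986,0.967,0.761,0.564
1347037,CaspC_ind,40,0.884,0.850,0.785,0.786,0.817,0.216
1347037,CaspC_ind,1,0.863,0.771,0.882,0.878,0.827,0.351
1347038,TRHR_ant,40,0.822,0.700,0.841,0.840,0.771,0.148
1347038,TRHR_ant,1,0.828,0.870,0.701,0.709,0.785,0.260
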
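locus,f_ins,ho
rs10590825,0.4924,0.4656
rs10607699,0.6489,0.4198
rs10626599,0.4733,0.4580
rs11277697,0.3798,0.4695
rs112879447,0.4447,0.5000
rs113011930,0.4561,0.4847
rs1160980,0.3855,0.4275
rs140683187,0.3569,0.4466
rs142221201,0.6603,0.4885
rs145010051,0.5038,0.4504
rs145191158,0.4561,0.5000
rs145577149,0.4027,0.4924
rs145941537,0.6355,0.4313
rs146875868,0.4160,0.5115
rs151335218,0.4599,0.4771
rs3064355,0.4294,0.4466
rs3067397,0.3149,0.4466
rs3076465,0.5095,0.4542
rs3217112,0.5725,0.5191
rs33971783,0.3931,0.5038
rs34076006,0.5076,0.4962
rs34287950,0.3779,0.5115
rs34419736,0.4198,0.4656
rs34421865,0.5878,0.5038
rs34529638,0.6469,0.4466
rs35065898,0.5706,0.5076
rs35309403,0.6221,0.4656
rs35453727,0.4046,0.4809
rs35464887,0.4523,0.5076
rs3834231,0.6393,0.4924
rs538690481,0.4237,0.4504
rs561160795,0.4160,0.5573
rs5787309,0.5382,0.4733
rs57981446,0.4828,0.4771
rs5897566,0.6355,0.4389
rs59841142,0.4637,0.5305
rs60564093,0.5840,0.5267
rs60867863,0.4771,0.5267
rs61490765,0.5248,0.5076
rs66477007,0.7328,0.3435
rs66595817,0.7290,0.3664
rs66739142,0.5210,0.4771
rs67100350,0.6393,0.4695
rs67264216,0.3760,0.4771
rs67365630,0.4943,0.4695
rs67405073,0.4237,0.4656
rs67426579,0.4637,0.5076
rs67487831,0.5630,0.4847
rs67939200,0.3760,0.4618
rs71852971,0.3206,0.4351
rs72031009,0.4637,0.5076
rs72085595,0.2901,0.4122
rs76158822,0.4828,0.5382
rs769299,0.5973,0.4618
rs77206391,0.4847,0.4962
rs77635204,0.5191,0.5191
rs79225518,0.4160,0.4656
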
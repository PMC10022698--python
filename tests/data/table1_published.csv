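locus,f_ins,f_del,he,ho,pic,pm,pd,pe,p_hw
rs10590825,0.4924,0.5076,0.5008,0.4656,0.3749,0.3597,0.6403,0.1592,0.2720
rs10607699,0.6489,0.3511,0.4566,0.4198,0.3519,0.3889,0.6111,0.1265,0.2360
rs10626599,0.4733,0.5267,0.4995,0.4580,0.3743,0.3581,0.6419,0.1533,0.2040
rs11277697,0.3798,0.6202,0.4720,0.4695,0.3601,0.3900,0.6100,0.1622,1.0000
rs112879447,0.4447,0.5553,0.4948,0.5000,0.3719,0.3811,0.6189,0.1875,0.9030
rs113011930,0.4561,0.5439,0.4971,0.4847,0.3731,0.3716,0.6284,0.1745,0.6930
rs1160980,0.3855,0.6145,0.4747,0.4275,0.3615,0.3729,0.6271,0.1315,0.1120
rs140683187,0.3569,0.6431,0.4599,0.4466,0.3537,0.3935,0.6065,0.1449,0.6840
rs142221201,0.6603,0.3397,0.4495,0.4885,0.3480,0.4209,0.5791,0.1777,0.1530
rs145010051,0.5038,0.4962,0.5009,0.4504,0.3750,0.3539,0.6461,0.1476,0.1040
rs145191158,0.4561,0.5439,0.4971,0.5000,0.3731,0.3789,0.6211,0.1875,1.0000
rs145577149,0.4027,0.5973,0.4820,0.4924,0.3653,0.3902,0.6098,0.1809,0.7600
rs145941537,0.6355,0.3645,0.4642,0.4313,0.3560,0.3844,0.6156,0.1341,0.2850
rs146875868,0.4160,0.5840,0.4868,0.5115,0.3678,0.3950,0.6050,0.1977,0.4530
rs151335218,0.4599,0.5401,0.4977,0.4771,0.3734,0.3675,0.6325,0.1682,0.5380
rs3064355,0.4294,0.5706,0.4910,0.4466,0.3700,0.3625,0.6375,0.1449,0.1520
rs3067397,0.3149,0.6851,0.4323,0.4466,0.3384,0.4211,0.5789,0.1449,0.6560
rs3076465,0.5095,0.4905,0.5008,0.4542,0.3749,0.3554,0.6446,0.1505,0.1430
rs3217112,0.5725,0.4275,0.4904,0.5191,0.3697,0.3956,0.6044,0.2048,0.3930
rs33971783,0.3931,0.6069,0.4781,0.5038,0.3633,0.3998,0.6002,0.1909,0.4610
rs34076006,0.5076,0.4924,0.5008,0.4962,0.3749,0.3732,0.6268,0.1842,0.9160
rs34287950,0.3779,0.6221,0.4711,0.5115,0.3596,0.4108,0.5892,0.1977,0.1970
rs34419736,0.4198,0.5802,0.4881,0.4656,0.3685,0.3724,0.6276,0.1592,0.5270
rs34421865,0.5878,0.4122,0.4855,0.5038,0.3672,0.3923,0.6077,0.1909,0.6020
rs34529638,0.6469,0.3531,0.4577,0.4466,0.3525,0.3958,0.6042,0.1449,0.7780
rs35065898,0.5706,0.4294,0.4910,0.5076,0.3700,0.3889,0.6111,0.1943,0.6380
rs35309403,0.6221,0.3779,0.4711,0.4656,0.3596,0.3894,0.6106,0.1592,0.9050
rs35453727,0.4046,0.5954,0.4827,0.4809,0.3657,0.3842,0.6158,0.1713,1.0000
rs35464887,0.4523,0.5477,0.4964,0.5076,0.3727,0.3835,0.6165,0.1943,0.8090
rs3834231,0.6393,0.3607,0.4621,0.4924,0.3548,0.4101,0.5899,0.1809,0.3410
rs538690481,0.4237,0.5763,0.4893,0.4504,0.3691,0.3655,0.6345,0.1476,0.2180
rs561160795,0.4160,0.5840,0.4868,0.5573,0.3678,0.4226,0.5774,0.2427,0.0200
rs5787309,0.5382,0.4618,0.4980,0.4733,0.3735,0.3656,0.6344,0.1652,0.4800
rs57981446,0.4828,0.5172,0.5004,0.4771,0.3747,0.3649,0.6351,0.1682,0.4720
rs5897566,0.6355,0.3645,0.4642,0.4389,0.3560,0.3868,0.6132,0.1394,0.4120
rs59841142,0.4637,0.5363,0.4983,0.5305,0.3737,0.3943,0.6057,0.2156,0.2990
rs60564093,0.5840,0.4160,0.4868,0.5267,0.3678,0.4035,0.5965,0.2120,0.2300
rs60867863,0.4771,0.5229,0.4999,0.5267,0.3745,0.3905,0.6095,0.2120,0.4020
rs61490765,0.5248,0.4752,0.4997,0.5076,0.3744,0.3801,0.6199,0.1943,0.8220
rs66477007,0.7328,0.2672,0.3923,0.3435,0.3149,0.4419,0.5581,0.0831,0.0640
rs66595817,0.7290,0.2710,0.3959,0.3664,0.3171,0.4399,0.5601,0.0948,0.2610
rs66739142,0.5210,0.4790,0.5001,0.4771,0.3746,0.3652,0.6348,0.1682,0.4640
rs67100350,0.6393,0.3607,0.4621,0.4695,0.3548,0.3999,0.6001,0.1622,0.8890
rs67264216,0.3760,0.6240,0.4701,0.4771,0.3591,0.3951,0.6049,0.1682,0.8940
rs67365630,0.4943,0.5057,0.5009,0.4695,0.3750,0.3612,0.6388,0.1622,0.3150
rs67405073,0.4237,0.5763,0.4893,0.4656,0.3691,0.3712,0.6288,0.1592,0.4200
rs67426579,0.4637,0.5363,0.4983,0.5076,0.3737,0.3815,0.6185,0.1943,0.7990
rs67487831,0.5630,0.4370,0.4930,0.4847,0.3710,0.3756,0.6244,0.1745,0.7890
rs67939200,0.3760,0.6240,0.4701,0.4618,0.3591,0.3889,0.6111,0.1562,0.8240
rs71852971,0.3206,0.6794,0.4365,0.4351,0.3407,0.4132,0.5868,0.1368,1.0000
rs72031009,0.4637,0.5363,0.4983,0.5076,0.3737,0.3815,0.6185,0.1943,0.8170
rs72085595,0.2901,0.7099,0.4127,0.4122,0.3270,0.4308,0.5692,0.1215,1.0000
rs76158822,0.4828,0.5172,0.5004,0.5382,0.3747,0.3969,0.6031,0.2231,0.2470
rs769299,0.5973,0.4027,0.4820,0.4618,0.3653,0.3770,0.6230,0.1562,0.5430
rs77206391,0.4847,0.5153,0.5005,0.4962,0.3748,0.3736,0.6264,0.1842,0.8860
rs77635204,0.5191,0.4809,0.5002,0.5191,0.3746,0.3858,0.6142,0.2048,0.6210
rs79225518,0.4160,0.5840,0.4868,0.4656,0.3678,0.3737,0.6263,0.1592,0.5180
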
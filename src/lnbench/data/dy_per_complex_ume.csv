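complex_id,ume_lnl,ume_full
AMAQDY,0.0517,0.1503
AKUKAT,0.0216,0.1148
BAFZUE,0.0470,0.1129
BEXLIA,0.0300,0.0972
BIHLIN,0.0317,0.0719
DANPEN,0.0410,0.0953
BUVXIZ01,0.0658,0.0872
DEKBEB,0.0438,0.0832
CECLIF,0.0522,0.0959
DEKBEB01,0.0370,0.0843
CECLIF10,0.0521,0.0960
DEKCAY01,0.0632,0.1068
DIBTIR,0.0313,0.0977
DUFCOW10,0.0348,0.1042
DIDBOH,0.0417,0.1567
FIGXEZ,0.0327,0.1403
FOPNAZ,0.0138,0.1471
FUXPAP01,0.1191,0.1026
FUXRAR,0.0401,0.1662
HIVWEP,0.0665,0.1222
GAKYEW,0.0258,0.1273
HOCYUU,0.0942,0.0976
GINPUO,0.0455,0.0813
IMOXAJ,0.0271,0.1036
HANCAA,0.0553,0.1424
KILZOU02,0.0487,0.1307
KITGEZ,0.0480,0.1391
KUYBIP,0.1338,0.1260
LEYHUS,0.0296,0.2200
LEZZOG,0.0343,0.0741
MANHOY,0.0804,0.1208
MECCUT,0.0408,0.1836
PALBIN,0.0205,0.4919
NAKMAO,0.0323,0.0713
QQQEMM01,0.0328,0.0841
NAPHAN,0.0377,0.0883
SETADY,0.0883,0.2516
OHUYUM,0.0286,0.0985
TISQUH,0.0670,0.1240
RABBEX,0.0825,0.2034
TUQTUU,0.0601,0.0940
ROCTIN,0.1118,0.2276
TUQTUU01,0.0601,0.0943
TESHEF,0.0348,0.1448
VOSBOU,0.0587,0.0879
TESHOP,0.0571,0.1010
XAWVIA,0.0408,0.1087
TESJEH,0.0356,0.1150
XEQMAH,0.0987,0.1019
TESJIL,0.0564,0.1008
XIVFUD,0.1015,0.2004
USEPEO,0.0484,0.1090
YAVSOD,0.0432,0.0726
WAQZEU,0.1499,0.1742
ZAXSAS,0.0700,0.1357
WAWJOT01,0.1152,0.1538
ZZZARG01,0.0602,0.0897
WEDHUJ,0.0282,0.1089
AGUTOL,0.0719,0.1019
XAYRIZ,0.0416,0.0874
AHANED,0.0817,0.1433
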
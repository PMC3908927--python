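complex_id,ume_lnl,ume_full
AERETS02,0.0563,0.0895
RIKTEK,0.0522,0.2208
AKIYEY,0.0440,0.2700
RIKTEK01,0.0488,0.2197
BAGBER,0.0462,0.1076
ROCSOS,0.0782,0.2444
BEXLEW,0.0842,0.1678
ROCTOT,0.0595,0.2138
BOBWAQ,0.0421,0.1184
RUNQOG,0.0513,0.1022
BODMUD,0.0388,0.1382
SEGVAB,0.0691,0.1681
BOWXOA,0.0450,0.1848
SOKBID,0.0280,0.0513
DEKCEC,0.0371,0.0914
TACERB01,0.0262,0.0958
DIBTAJ,0.0369,0.1778
TEJFEU,0.1355,0.2048
DIDCAU,0.0399,0.2601
TEPKOO,0.0297,0.0715
DIJQAO,0.0391,0.2332
TMHDER,0.0588,0.3224
DIJQIW,0.0310,0.1024
TUMJEQ,0.0583,0.1227
DIYNII,0.0260,0.1158
UFIRIK,0.0622,0.0716
DOGKEP,0.0323,0.1502
VEQFOM,0.0820,0.0617
GAKYOG,0.0266,0.1057
VOSNOG,0.0375,0.0833
GINRIE,0.0464,0.0807
VUSGUL,0.0817,0.0941
HANCOO,0.0165,0.0609
VUSHEW,0.0593,0.1107
HEDVIW,0.1052,0.1989
WEFVIM,0.0466,0.0843
HENAEB,0.0283,0.1548
XAXYAX,0.0593,0.0854
KITGUP,0.0149,0.0729
XEWVOK,0.0442,0.1163
KOZBUW,0.0144,0.0561
XEWWUR,0.0472,0.0938
LEYJII,0.0294,0.2276
XOVHAS,0.0851,0.2268
MAGDOP,0.0449,0.1319
XOYXIS,0.0285,0.1590
MECDEE,0.0281,0.0853
YEGFEV,0.0504,0.1687
NIVQUE,0.0499,0.2188
YEMSIT,0.0767,0.1338
NUYNUR,0.0838,0.2163
YICCIW,0.0344,0.1527
OHUZEX,0.0269,0.0890
YUFWIG,0.0196,0.0988
OMATUS,0.0742,0.1597
ZADWUW,0.1281,0.2265
QIVXID,0.0742,0.2170
ZUFSAU,0.0480,0.1304
RELNIG,0.0530,0.1011
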
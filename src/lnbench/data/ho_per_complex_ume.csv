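complex_id,ume_lnl,ume_full
BAGBAN,0.0513,0.1131
XARVOB,0.0363,0.0912
BEYSAZ,0.0529,0.1976
XAWVOG,0.0530,0.0930
BUVXOF01,0.0634,0.0869
XEQMEL,0.0843,0.0602
CAQFUV,0.0676,0.0790
XEWVIE,0.0696,0.1305
COZHEE,0.0223,0.0966
XORGEQ,0.0362,0.4482
CUSYUK,0.0483,0.2318
AGUVED,0.0443,0.0838
ECOJEL,0.0975,0.1573
AXAZAA,0.0893,0.1137
FAGYOC,0.0695,0.3482
DEKBAX,0.0378,0.0768
GAKYIA,0.0462,0.1312
DEKBOL,0.1163,0.1557
GINREA,0.0460,0.0775
EWIPUV,0.0365,0.1275
GODKOZ,0.0358,0.0523
FUXRIZ,0.0742,0.0715
HANCII,0.0196,0.0593
GIFLIQ,0.1142,0.1489
HOESUL02,0.0621,0.0916
MOGWUB,0.4893,0.6047
KITGOJ,0.0254,0.0773
MUHWIW,0.0491,0.0888
LEYJEE,0.0413,0.1874
NUFQAG,0.0399,0.0715
LIZPAL,0.0499,0.2272
NUYNOL,0.0689,0.0652
NIHRIF,0.0640,0.1070
NUYNOL01,0.0484,0.0764
NUJBAV,0.0087,0.0625
QELLOJ,0.0493,0.0937
QOZVOQ,0.0185,0.1002
QIVYAW,0.0423,0.0620
SIFZIQ,0.0273,0.1721
YEFVUA,0.0349,0.0760
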
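distance_type,n,rm1,sparkle_rm1,sparkle_pm7,sparkle_pm6,sparkle_pm3,sparkle_am1
Er - Er,6,0.1200,0.2639,0.5458,0.2124,0.2439,0.2626
Er - O,336,0.0509,0.0730,0.0874,0.1285,0.0657,0.0689
Er - N,77,0.0594,0.0484,0.0529,0.0846,0.0551,0.0434
Er - C,96,0.0318,0.2004,0.4280,0.5474,0.2277,0.2177
Er - S,12,0.1088,0.4802,1.2501,0.5234,0.5211,0.5212
Er - Cl,33,0.0574,0.3243,0.3406,0.2753,0.2975,0.2928
Er - Br,3,0.0463,0.4526,1.5964,0.4475,0.4146,0.4291
Er - L,563,0.0511,0.1199,0.1967,0.2136,0.1205,0.1189
L - L',2259,0.1575,0.2197,0.2938,0.3519,0.2076,0.2371
"Er-L, Er-Er and L-L'",2822,0.1363,0.2000,0.2746,0.3243,0.1904,0.2137
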
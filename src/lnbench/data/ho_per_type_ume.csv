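distance_type,n,rm1,sparkle_rm1,sparkle_pm7,sparkle_pm6,sparkle_pm3,sparkle_am1
Ho - Ho,4,0.1301,0.2083,0.2144,0.2751,0.1958,0.2747
Ho - O,219,0.0475,0.0604,0.0554,0.1021,0.0639,0.0557
Ho - N,58,0.0786,0.0696,0.1592,0.1732,0.0585,0.0469
Ho - C,98,0.0752,0.2256,0.4544,0.5380,0.2537,0.2655
Ho - Cl,28,0.0585,0.3055,0.1262,0.2777,0.2480,0.2679
Ho - L,407,0.0602,0.1198,0.1727,0.2310,0.1228,0.1217
L - L',1748,0.1371,0.2326,0.3289,0.3462,0.2324,0.2585
"Ho-L, Ho-Ho and L-L",2155,0.1225,0.2113,0.2994,0.3245,0.2117,0.2327
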
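distance_type,n,rm1,sparkle_rm1,sparkle_pm7,sparkle_pm6,sparkle_pm3,sparkle_am1
Dy - Dy,16,0.2118,0.2397,0.5950,0.5025,0.1784,0.2531
Dy - O,283,0.0637,0.0760,0.0692,0.1259,0.0685,0.0740
Dy - N,105,0.0594,0.0510,0.2084,0.0992,0.0741,0.0500
Dy - C,315,0.0341,0.1854,0.2567,0.4616,0.2346,0.2161
Dy - S,21,0.0824,0.5016,0.9833,0.5359,0.4996,0.5019
Dy - P,3,0.0273,0.1591,2.3194,0.3934,0.4205,0.3918
Dy - Cl,20,0.0525,0.2858,0.1757,0.2318,0.2475,0.2546
Dy - Br,5,0.0311,0.4564,1.3418,0.3986,0.4209,0.4320
Dy - L,768,0.0539,0.1408,0.2209,0.2846,0.1598,0.1527
L-L',3499,0.1336,0.2370,0.2931,0.3449,0.2433,0.2621
"Dy-L, Dy-Dy and L-L'",4267,0.1193,0.2197,0.2801,0.3341,0.2283,0.2424
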
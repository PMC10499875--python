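unshare_berkson,share_berkson,unshare_class,share_class,corr,unadjusted_coverage_alpha,unadjusted_coverage_beta,rc_coverage_alpha,rc_coverage_beta,erc_coverage_alpha,erc_coverage_beta,mcml_coverage_alpha,mcml_coverage_beta,unadjusted_alpha,unadjusted_beta,rc_alpha,rc_beta,erc_alpha,erc_beta,mcml_alpha,mcml_beta
0.0,0.0,0.2,0.2,,95.0,80.8,95.2,94.8,95.2,94.8,95.2,94.8,0.221,2.278,0.196,2.061,0.196,2.061,0.196,2.061
0.0,0.0,0.2,0.5,,94.4,55.4,95.2,94.8,95.2,94.8,95.2,94.8,0.288,4.168,0.196,2.061,0.196,2.061,0.196,2.061
0.0,0.0,0.5,0.2,,94.4,79.6,95.2,94.8,95.2,94.8,95.2,94.8,0.255,2.260,0.196,2.061,0.196,2.061,0.196,2.061
0.0,0.0,0.5,0.5,,94.6,55.0,95.2,94.8,95.2,94.8,95.2,94.8,0.328,4.136,0.196,2.061,0.196,2.061,0.196,2.061
0.2,0.2,0.2,0.2,0.50,95.0,80.0,95.4,94.0,94.8,98.4,95.4,99.0,0.220,2.469,0.195,2.233,0.125,2.132,0.288,2.207
0.2,0.2,0.2,0.5,0.50,94.8,53.6,95.4,94.0,94.8,98.4,95.4,99.0,0.287,4.523,0.195,2.233,0.125,2.132,0.288,2.207
0.2,0.2,0.5,0.2,0.50,94.6,78.2,95.4,94.0,94.8,98.4,95.4,99.0,0.255,2.451,0.195,2.233,0.125,2.132,0.288,2.207
0.2,0.2,0.5,0.5,0.50,94.6,52.2,95.4,94.0,94.8,98.4,95.4,99.0,0.328,4.492,0.195,2.233,0.125,2.132,0.288,2.207
0.2,0.5,0.2,0.2,0.84,93.6,77.4,94.4,85.6,95.4,94.8,95.0,100.0,0.262,2.983,0.227,2.707,0.109,2.393,0.370,3.007
0.2,0.5,0.2,0.5,0.84,93.2,48.4,94.4,85.6,95.4,94.8,95.0,100.0,0.354,5.426,0.227,2.707,0.109,2.393,0.370,3.007
0.2,0.5,0.5,0.2,0.84,93.8,75.4,94.4,85.6,95.4,94.8,95.0,100.0,0.303,2.962,0.227,2.707,0.109,2.393,0.370,3.007
0.2,0.5,0.5,0.5,0.84,93.8,48.2,94.4,85.6,95.4,94.8,95.0,100.0,0.401,5.390,0.227,2.707,0.109,2.393,0.370,3.007
0.5,0.2,0.2,0.2,0.15,94.2,76.6,94.0,86.0,94.4,94.8,95.0,99.2,0.259,2.986,0.224,2.709,0.121,2.354,0.337,2.678
0.5,0.2,0.2,0.5,0.15,93.4,48.4,94.0,86.0,94.4,94.8,95.0,99.2,0.347,5.441,0.224,2.709,0.121,2.354,0.337,2.678
0.5,0.2,0.5,0.2,0.15,94.0,75.6,94.0,86.0,94.4,94.8,95.0,99.2,0.299,2.964,0.224,2.709,0.121,2.354,0.337,2.678
0.5,0.2,0.5,0.5,0.15,94.0,49.0,94.0,86.0,94.4,94.8,95.0,99.2,0.395,5.401,0.224,2.709,0.121,2.354,0.337,2.678
0.5,0.5,0.2,0.2,0.45,95.4,64.0,95.4,67.8,95.0,80.4,96.4,100.0,0.243,3.703,0.209,3.349,0.038,2.795,0.362,3.401
0.5,0.5,0.2,0.5,0.45,95.0,40.0,95.4,67.8,95.0,80.4,96.4,100.0,0.332,6.744,0.209,3.349,0.038,2.795,0.362,3.401
0.5,0.5,0.5,0.2,0.45,94.4,64.6,95.4,67.8,95.0,80.4,96.4,100.0,0.286,3.682,0.209,3.349,0.038,2.795,0.362,3.401
0.5,0.5,0.5,0.5,0.45,94.2,40.0,95.4,67.8,95.0,80.4,96.4,100.0,0.383,6.703,0.209,3.349,0.038,2.795,0.362,3.401
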
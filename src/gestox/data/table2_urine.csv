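# Reference urine screening report: correlation loading r and H/C fold change
# for each within-day comparison; "/" marks |r| < 0.666.
metabolite,r_C8-H8,fc_C8-H8,r_C11-H11,fc_C11-H11,r_C14-H14,fc_C14-H14,r_C17-H17,fc_C17-H17,r_C20-H20,fc_C20-H20
1-Methylhistidine,-0.807,0.867,/,0.862,/,1.058,/,1.044,/,0.792
2-Hydroxybutyrate,/,0.949,/,1.076,-0.841,0.976,-0.89,0.939,0.92,1.255
3-Hydroxybutyrate,/,0.978,/,0.981,-0.892,0.851,-0.89,0.783,-0.853,1.045
Acetoacetate,/,0.922,/,1.004,-0.861,0.753,-0.867,0.67,/,1.165
Acetone,-0.901,0.783,/,1.03,-0.903,0.668,-0.965,0.563,/,1.213
Allantoin,/,1.071,-0.673,0.814,/,1.047,/,1.195,/,0.911
Aminoadipate,-0.887,0.661,/,1.106,-0.898,0.685,-0.814,0.724,/,1.259
Benzoate,/,0.84,-0.805,0.846,-0.746,0.786,-0.806,0.825,/,1.027
Butyrate,/,0.777,/,0.947,-0.849,0.805,-0.922,0.751,0.829,1.362
cis-Aconitate,/,1.152,-0.724,0.518,/,1.284,/,0.65,-0.678,0.422
Citrate,/,1.86,0.831,1.815,/,1.292,/,0.882,/,0.817
Fumarate,-0.882,0.367,/,0.672,/,0.543,/,0.45,/,1.13
Glycine,/,1.12,/,1.082,/,1.208,/,1.064,0.811,1.143
Hippurate,/,1.035,/,1.053,0.729,1.437,0.923,1.487,-0.807,0.76
Hydroxypyruvate,/,1.088,/,0.909,/,1.235,/,1.123,-0.812,0.822
Lactate,-0.897,0.695,/,1.201,-0.888,0.713,-0.956,0.589,/,0.986
Malate,0.891,1.23,/,0.905,/,1.189,0.917,1.308,-0.915,0.72
Maleicate,/,0.937,-0.835,0.778,/,0.969,/,1.221,/,0.972
"N,N-Dimethylglycine",-0.942,0.713,/,1.14,/,0.692,/,0.847,/,1.932
N-Acetylaspartate,0.809,1,/,0.965,/,1.095,/,1.114,0.87,1.08
N-Acetylglutamate,/,0.916,/,1.141,/,0.979,-0.926,0.965,/,1.125
ortho-Hydroxyphenylacetate,/,0.902,/,0.953,/,0.909,/,0.905,-0.686,0.647
Phenylacetylglycine,0.786,1.178,-0.845,0.787,-0.813,1.086,-0.858,0.971,/,0.905
Picolinate,/,0.934,/,1.014,-0.706,1.087,0.789,1.346,0.785,1.011
Succinate,/,1.151,/,1.35,/,1.16,/,0.908,-0.736,0.764
Taurine,/,0.827,/,0.761,/,0.884,/,0.984,0.868,1.467
Trigonelline,/,1.176,0.764,1.425,/,1.428,/,1.875,-0.842,0.777
Urocanate,-0.793,0.552,/,1.012,/,0.796,/,0.907,/,0.913
α-Ketoglutarate,0.718,1.612,0.859,1.998,/,1.29,/,0.879,/,0.981
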
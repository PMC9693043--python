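# Reference plasma screening report: correlation loading r and H/C fold change
# for each within-day comparison; "/" marks |r| < 0.666 (r columns) or an
# unreliable fold change (broad lipoprotein/lipid envelopes).
metabolite,r_C8-H8,fc_C8-H8,r_C11-H11,fc_C11-H11,r_C14-H14,fc_C14-H14,r_C17-H17,fc_C17-H17,r_C20-H20,fc_C20-H20
3-Hydroxybutyrate,/,0.998,-0.821,0.715,-0.865,0.548,-0.881,0.415,-0.797,0.755
Acetoacetate,/,1.23,/,0.791,/,0.522,-0.797,0.475,-0.712,0.704
Acetate,/,1.021,-0.688,0.845,-0.792,0.856,/,0.844,/,0.925
Acetone,/,1.416,/,0.972,-0.822,0.743,-0.814,0.446,-0.706,0.829
Benzoate,-0.675,0.907,/,0.905,/,0.92,/,0.58,/,1.08
cis-Aconitate,0.738,0.974,/,1.09,/,1.237,/,1.578,/,0.208
Choline,/,0.91,-0.886,0.923,-0.72,0.82,/,0.927,-0.777,1.011
Citrate,/,0.862,-0.785,0.848,-0.804,0.818,-0.791,0.954,/,0.973
Creatine,/,0.818,/,0.843,-0.689,0.734,/,0.857,/,1.148
Cytidine,/,0.899,-0.698,0.863,-0.722,0.728,/,1.349,/,1.082
Deoxyguanosine,/,0.975,-0.676,0.776,/,0.724,/,1.543,0.804,1.786
"N,N-Dimethylglycin",/,0.987,-0.835,0.846,/,0.871,/,0.972,/,1.006
Ethanolamine,/,0.917,-0.782,0.918,/,0.996,/,1.185,/,1.122
Fumarate,/,0.551,/,0.129,/,0.126,/,0.043,0.741,1.729
Glutamine,-0.718,0.961,-0.815,0.919,/,0.925,-0.831,0.894,/,1.053
Glycerol,/,0.926,-0.781,0.918,-0.853,0.862,/,0.932,/,1.038
Isobutyrate,/,1.054,/,0.862,-0.782,0.807,-0.693,0.8,/,1.055
Isoleucine,/,1.08,/,0.966,/,0.968,-0.831,0.872,-0.827,0.906
Lipid,0.726,/,-0.764,/,-0.827,/,/,/,-0.702,/
VLDL,0.681,/,/,/,/,/,/,/,-0.909,/
LDL,/,/,/,/,/,/,/,/,-0.884,/
Lactate,/,0.927,/,0.793,/,1.036,/,0.811,0.834,1.132
Leucine,0.691,1.087,/,0.996,/,0.995,-0.805,0.815,-0.8,0.979
Lysine,/,1.096,-0.92,0.818,-0.774,0.887,-0.809,0.784,/,0.934
Methionine,/,0.944,-0.916,0.839,-0.797,0.909,/,0.902,/,1.002
Phenylalanine,/,0.969,-0.785,0.892,-0.778,0.85,-0.766,0.745,/,0.967
Sarcosine,/,0.971,-0.718,0.898,-0.772,0.916,/,0.956,/,1.007
Serine,/,0.95,-0.686,0.896,-0.764,0.855,/,0.972,/,0.947
Threonine,/,1.01,/,0.964,-0.907,0.834,/,0.982,-0.754,0.961
Valine,0.844,1.108,/,0.915,/,1.014,-0.817,0.874,/,0.994
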
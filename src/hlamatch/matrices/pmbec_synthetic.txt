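#  SYNTHETIC covariance-style amino-acid similarity matrix.
#  Built as the correlation of per-residue physicochemical descriptor
#  profiles (hydropathy, volume, polarity, charge, isoelectric point).
#  It stands in for a peptide:MHC binding-energy covariance matrix and
#  carries no experimental binding data.
   A      R      N      D      C      Q      E      G      H      I      L      K      M      F      P      S      T      W      Y      V
A  1.000 -0.333 -0.053 -0.097  0.716 -0.504 -0.281  0.858 -0.476  0.242  0.178 -0.319  0.027 -0.156  0.489  0.769  0.758 -0.755 -0.782  0.531
R -0.333  1.000  0.317 -0.351 -0.565  0.451 -0.342  0.050  0.816 -0.599 -0.536  0.983 -0.488 -0.512  0.636  0.039 -0.069 -0.012  0.031 -0.641
N -0.053  0.317  1.000  0.688 -0.650  0.889  0.590  0.416  0.641 -0.941 -0.963  0.455 -0.960 -0.906  0.406  0.584  0.576 -0.603 -0.554 -0.834
D -0.097 -0.351  0.688  1.000 -0.472  0.623  0.975  0.094  0.221 -0.507 -0.562 -0.249 -0.572 -0.452 -0.211  0.262  0.288 -0.345 -0.346 -0.464
C  0.716 -0.565 -0.650 -0.472  1.000 -0.896 -0.551  0.290 -0.902  0.809  0.777 -0.599  0.694  0.554 -0.067  0.160  0.226 -0.104 -0.135  0.937
Q -0.504  0.451  0.889  0.623 -0.896  1.000  0.622 -0.028  0.788 -0.932 -0.920  0.561 -0.849 -0.721  0.147  0.155  0.149 -0.178 -0.123 -0.971
E -0.281 -0.342  0.590  0.975 -0.551  0.622  1.000 -0.117  0.250 -0.450 -0.492 -0.262 -0.479 -0.328 -0.358  0.048  0.070 -0.141 -0.146 -0.473
G  0.858  0.050  0.416  0.094  0.290 -0.028 -0.117  1.000 -0.000 -0.283 -0.338  0.111 -0.472 -0.633  0.788  0.976  0.932 -0.965 -0.964  0.026
H -0.476  0.816  0.641  0.221 -0.902  0.788  0.250 -0.000  1.000 -0.857 -0.821  0.827 -0.777 -0.722  0.467  0.068 -0.053 -0.113 -0.083 -0.908
I  0.242 -0.599 -0.941 -0.507  0.809 -0.932 -0.450 -0.283 -0.857  1.000  0.996 -0.699  0.970  0.914 -0.493 -0.424 -0.372  0.444  0.394  0.951
L  0.178 -0.536 -0.963 -0.562  0.777 -0.920 -0.492 -0.338 -0.821  0.996  1.000 -0.642  0.986  0.934 -0.497 -0.482 -0.433  0.508  0.461  0.926
K -0.319  0.983  0.455 -0.249 -0.599  0.561 -0.262  0.111  0.827 -0.699 -0.642  1.000 -0.588 -0.602  0.646  0.133  0.049 -0.097 -0.042 -0.721
M  0.027 -0.488 -0.960 -0.572  0.694 -0.849 -0.479 -0.472 -0.777  0.970  0.986 -0.588  1.000  0.976 -0.582 -0.598 -0.535  0.633  0.595  0.856
F -0.156 -0.512 -0.906 -0.452  0.554 -0.721 -0.328 -0.633 -0.722  0.914  0.934 -0.602  0.976  1.000 -0.735 -0.724 -0.644  0.751  0.718  0.750
P  0.489  0.636  0.406 -0.211 -0.067  0.147 -0.358  0.788  0.467 -0.493 -0.497  0.646 -0.582 -0.735  1.000  0.733  0.613 -0.718 -0.703 -0.284
S  0.769  0.039  0.584  0.262  0.160  0.155  0.048  0.976  0.068 -0.424 -0.482  0.133 -0.598 -0.724  0.733  1.000  0.978 -0.989 -0.975 -0.122
T  0.758 -0.069  0.576  0.288  0.226  0.149  0.070  0.932 -0.053 -0.372 -0.433  0.049 -0.535 -0.644  0.613  0.978  1.000 -0.948 -0.926 -0.078
W -0.755 -0.012 -0.603 -0.345 -0.104 -0.178 -0.141 -0.965 -0.113  0.444  0.508 -0.097  0.633  0.751 -0.718 -0.989 -0.948  1.000  0.996  0.146
Y -0.782  0.031 -0.554 -0.346 -0.135 -0.123 -0.146 -0.964 -0.083  0.394  0.461 -0.042  0.595  0.718 -0.703 -0.975 -0.926  0.996  1.000  0.094
V  0.531 -0.641 -0.834 -0.464  0.937 -0.971 -0.473  0.026 -0.908  0.951  0.926 -0.721  0.856  0.750 -0.284 -0.122 -0.078  0.146  0.094  1.000
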
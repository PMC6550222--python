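#  BLOSUM50 amino-acid substitution matrix (half-bit units).
#  Entries for ambiguity codes B/Z/X and the stop symbol * are included
#  as in the standard NCBI distribution of this matrix.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V  B  Z  X  *
A   5  -2  -1  -2  -1  -1  -1   0  -2  -1  -2  -1  -1  -3  -1   1   0  -3  -2   0  -2  -1  -1  -5
R  -2   7  -1  -2  -4   1   0  -3   0  -4  -3   3  -2  -3  -3  -1  -1  -3  -1  -3  -1   0  -1  -5
N  -1  -1   7   2  -2   0   0   0   1  -3  -4   0  -2  -4  -2   1   0  -4  -2  -3   4   0  -1  -5
D  -2  -2   2   8  -4   0   2  -1  -1  -4  -4  -1  -4  -5  -1   0  -1  -5  -3  -4   5   1  -1  -5
C  -1  -4  -2  -4  13  -3  -3  -3  -3  -2  -2  -3  -2  -2  -4  -1  -1  -5  -3  -1  -3  -3  -2  -5
Q  -1   1   0   0  -3   7   2  -2   1  -3  -2   2   0  -4  -1   0  -1  -1  -1  -3   0   4  -1  -5
E  -1   0   0   2  -3   2   6  -3   0  -4  -3   1  -2  -3  -1  -1  -1  -3  -2  -3   1   5  -1  -5
G   0  -3   0  -1  -3  -2  -3   8  -2  -4  -4  -2  -3  -4  -2   0  -2  -3  -3  -4  -1  -2  -2  -5
H  -2   0   1  -1  -3   1   0  -2  10  -4  -3   0  -1  -1  -2  -1  -2  -3   2  -4   0   0  -1  -5
I  -1  -4  -3  -4  -2  -3  -4  -4  -4   5   2  -3   2   0  -3  -3  -1  -3  -1   4  -4  -3  -1  -5
L  -2  -3  -4  -4  -2  -2  -3  -4  -3   2   5  -3   3   1  -4  -3  -1  -2  -1   1  -4  -3  -1  -5
K  -1   3   0  -1  -3   2   1  -2   0  -3  -3   6  -2  -4  -1   0  -1  -3  -2  -3   0   1  -1  -5
M  -1  -2  -2  -4  -2   0  -2  -3  -1   2   3  -2   7   0  -3  -2  -1  -1   0   1  -3  -1  -1  -5
F  -3  -3  -4  -5  -2  -4  -3  -4  -1   0   1  -4   0   8  -4  -3  -2   1   4  -1  -4  -4  -2  -5
P  -1  -3  -2  -1  -4  -1  -1  -2  -2  -3  -4  -1  -3  -4  10  -1  -1  -4  -3  -3  -2  -1  -2  -5
S   1  -1   1   0  -1   0  -1   0  -1  -3  -3   0  -2  -3  -1   5   2  -4  -2  -2   0   0  -1  -5
T   0  -1   0  -1  -1  -1  -1  -2  -2  -1  -1  -1  -1  -2  -1   2   5  -3  -2   0   0  -1   0  -5
W  -3  -3  -4  -5  -5  -1  -3  -3  -3  -3  -2  -3  -1   1  -4  -4  -3  15   2  -3  -5  -2  -3  -5
Y  -2  -1  -2  -3  -3  -1  -2  -3   2  -1  -1  -2   0   4  -3  -2  -2   2   8  -1  -3  -2  -1  -5
V   0  -3  -3  -4  -1  -3  -3  -4  -4   4   1  -3   1  -1  -3  -2   0  -3  -1   5  -4  -3  -1  -5
B  -2  -1   4   5  -3   0   1  -1   0  -4  -4   0  -3  -4  -2   0   0  -5  -3  -4   5   2  -1  -5
Z  -1   0   0   1  -3   4   5  -2   0  -3  -3   1  -1  -4  -1   0  -1  -2  -2  -3   2   5  -1  -5
X  -1  -1  -1  -1  -2  -1  -1  -2  -1  -1  -1  -1  -1  -2  -2  -1   0  -3  -1  -1  -1  -1  -1  -5
*  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5  -5   1
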
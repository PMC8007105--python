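# side-chain contact potential, -log f(sigma, tau)
          A         C         D         E         F         G         H         I         K         L         M         N         P         Q         R         S         T         V         W         Y
A   6.70257   5.31628   5.60396   6.99026   5.89164   5.89164   5.78628   6.14296   5.89164   5.44981   5.60396   6.00943   6.29711   5.44981   6.29711   6.00943   6.29711   5.89164   5.52392   5.52392
C   5.31628   6.14296   5.89164   5.78628   6.14296   5.60396   5.78628   5.78628   6.99026   6.14296   6.29711   6.29711   6.14296   6.29711   6.99026   5.78628   5.89164   6.29711   5.19850   6.14296
D   5.60396   5.89164   7.39572   6.29711   6.70257   5.89164   5.60396   5.44981   6.99026   5.60396   6.47943   6.00943   6.14296   5.78628   6.47943   6.00943   5.69097   6.29711   5.44981   5.52392
E   6.99026   5.78628   6.29711   6.47943   6.00943   6.47943   6.47943   6.47943   6.99026   5.69097   6.47943   6.00943   5.69097   6.47943   6.00943   6.70257   6.14296   6.29711   6.29711   6.70257
F   5.89164   6.14296   6.70257   6.00943   6.29711   5.78628   6.00943   5.52392   6.47943   5.69097   6.00943   6.29711   6.14296   6.14296   6.00943   5.89164   5.69097   6.00943   5.31628   6.00943
G   5.89164   5.60396   5.89164   6.47943   5.78628   6.70257   6.29711   5.89164   5.78628   5.60396   6.47943   5.69097   5.69097   6.29711   6.14296   6.14296   5.89164   5.78628   5.89164   6.29711
H   5.78628   5.78628   5.60396   6.47943   6.00943   6.29711   6.99026   6.00943   6.47943   6.47943   6.14296   6.00943   6.00943   5.60396   6.99026   5.69097   6.29711   6.14296   5.78628   6.14296
I   6.14296   5.78628   5.44981   6.47943   5.52392   5.89164   6.00943   6.14296   6.99026   5.60396   6.47943   6.14296   5.31628   5.89164   5.78628   5.78628   6.29711   6.00943   6.29711   6.14296
K   5.89164   6.99026   6.99026   6.99026   6.47943   5.78628   6.47943   6.99026   6.99026   6.00943   6.14296   6.00943   7.39572   6.47943   6.99026   6.29711   7.39572   6.14296   6.14296   6.47943
L   5.44981   6.14296   5.60396   5.69097   5.69097   5.60396   6.47943   5.60396   6.00943   6.47943   5.38082   6.00943   5.38082   5.69097   5.78628   5.69097   5.31628   6.00943   5.69097   5.78628
M   5.60396   6.29711   6.47943   6.47943   6.00943   6.47943   6.14296   6.47943   6.14296   5.38082   7.39572   6.14296   6.47943   5.78628   5.78628   6.14296   6.47943   6.47943   6.00943   5.78628
N   6.00943   6.29711   6.00943   6.00943   6.29711   5.69097   6.00943   6.14296   6.00943   6.00943   6.14296   6.99026   6.14296   6.14296   6.29711   6.14296   6.14296   6.70257   6.14296   5.69097
P   6.29711   6.14296   6.14296   5.69097   6.14296   5.69097   6.00943   5.31628   7.39572   5.38082   6.47943   6.14296   6.29711   6.29711   6.29711   5.44981   5.69097   6.00943   5.89164   6.14296
Q   5.44981   6.29711   5.78628   6.47943   6.14296   6.29711   5.60396   5.89164   6.47943   5.69097   5.78628   6.14296   6.29711   6.70257   6.00943   6.47943   6.00943   6.00943   6.00943   6.29711
R   6.29711   6.99026   6.47943   6.00943   6.00943   6.14296   6.99026   5.78628   6.99026   5.78628   5.78628   6.29711   6.29711   6.00943   6.70257   6.29711   5.52392   5.69097   6.00943   5.69097
S   6.00943   5.78628   6.00943   6.70257   5.89164   6.14296   5.69097   5.78628   6.29711   5.69097   6.14296   6.14296   5.44981   6.47943   6.29711   7.39572   5.78628   5.89164   5.52392   6.14296
T   6.29711   5.89164   5.69097   6.14296   5.69097   5.89164   6.29711   6.29711   7.39572   5.31628   6.47943   6.14296   5.69097   6.00943   5.52392   5.78628   6.47943   5.44981   5.89164   5.89164
V   5.89164   6.29711   6.29711   6.29711   6.00943   5.78628   6.14296   6.00943   6.14296   6.00943   6.47943   6.70257   6.00943   6.00943   5.69097   5.89164   5.44981   6.99026   5.19850   6.00943
W   5.52392   5.19850   5.44981   6.29711   5.31628   5.89164   5.78628   6.29711   6.14296   5.69097   6.00943   6.14296   5.89164   6.00943   6.00943   5.52392   5.89164   5.19850   7.39572   5.52392
Y   5.52392   6.14296   5.52392   6.70257   6.00943   6.29711   6.14296   6.14296   6.47943   5.78628   5.78628   5.69097   6.14296   6.29711   5.69097   6.14296   5.89164   6.00943   5.52392   6.47943
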
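ATOM      1  N   TYR A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  TYR A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   TYR A   1       2.005   0.000   1.419  1.00  0.00           C
ATOM      4  O   TYR A   1       3.218  -0.000   1.622  1.00  0.00           O
ATOM      5  CB  TYR A   1       1.996  -1.215  -0.759  1.00  0.00           C
ATOM      6  CG  TYR A   1       3.504  -1.271  -0.794  1.00  0.00           C
ATOM      7  CD1 TYR A   1       4.251  -0.277  -0.173  1.00  0.00           C
ATOM      8  CD2 TYR A   1       4.146  -2.317  -1.448  1.00  0.00           C
ATOM      9  CE1 TYR A   1       5.640  -0.328  -0.205  1.00  0.00           C
ATOM     10  CE2 TYR A   1       5.535  -2.368  -1.480  1.00  0.00           C
ATOM     11  CZ  TYR A   1       6.282  -1.374  -0.859  1.00  0.00           C
ATOM     12  OH  TYR A   1       7.660  -1.425  -0.890  1.00  0.00           O
ATOM     13  H   TYR A   1      -0.474   0.000  -0.892  1.00  0.00           H
ATOM     14  HH  TYR A   1       8.019  -0.670  -0.418  1.00  0.00           H
END
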
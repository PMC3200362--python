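HETATM    1  O1  TTA T   1       0.000  -0.371  -0.001  1.00  0.00           O
HETATM    2  N1  TTB T   2       7.000   0.101  -0.471  1.00  0.00           N
HETATM    3 FE   TTR T   3      14.000  -0.352   0.428  1.00  0.00          FE
END
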
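REMARK 300 pocketsim v0.1.0
REMARK 300 params: cutoff=4.0 epsilon=3.0 merge_level=pseudocenter
REMARK 300 input pdb0: site0.pdb sha256:e20e748e2bd1af46
REMARK 300 input pdb1: site1.pdb sha256:8ac9fb45c6070aa3
REMARK 300 input pdb2: site2.pdb sha256:93ff622bbdffcc17
HETATM    1  C   ALI M   1       7.199  -1.290  -1.841  1.00  3.00           C
HETATM    2  C   DON M   2       9.622   0.383  -1.293  1.00  3.00           C
HETATM    3  C   ACC M   3       4.383  -5.242  -3.036  1.00  3.00           C
HETATM    4  C   ALI M   4       2.863   3.693   2.366  1.00  3.00           C
HETATM    5  C   DON M   5       4.961   1.921   3.338  1.00  3.00           C
HETATM    6  C   DAC M   6      -0.498   4.511  -3.075  1.00  3.00           C
HETATM    7  C   ALI M   7       2.725  -3.617   2.284  1.00  3.00           C
HETATM    8  C   DON M   8      -0.158   4.424   3.994  1.00  3.00           C
HETATM    9  C   ACC M   9      -0.561   1.962   3.332  1.00  3.00           C
HETATM   10  C   ACC M  10      -1.193  -0.164   6.354  1.00  3.00           C
END
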
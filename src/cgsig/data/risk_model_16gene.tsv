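gene	coefficient
RCAN3	-0.027
MCOLN2	-0.130
DENND2D	-0.047
RWDD3	-0.019
ZMYM6	-0.022
CAPZA1	-0.029
TRIM45	0.049
GPR18	-0.156
WARS2	0.011
SCRN1	0.013
CSNK1E	0.011
HBXIP	-0.007
MRPL20	-0.004
CSDE1	-0.017
COL20A1	0.001
IKZF1	-0.179
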
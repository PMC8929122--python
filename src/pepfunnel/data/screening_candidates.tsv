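sequence	binding_pvalue	known_dppiv_inhibitor
PR	1.45e-4	no
IP	1.98e-4	yes
LP	2.07e-4	yes
LPQ	4.91e-4	yes
FT	1.49e-3	no
SIPR	1.77e-3	no
GI	2.07e-3	yes
MI	2.12e-3	yes
SAPI	2.23e-3	no
ML	2.25e-3	yes
GL	3.53e-3	yes
FVPH	3.56e-3	no
VF	3.63e-3	yes
FV	3.63e-3	no
AL	5.87e-3	yes
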
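sequence	activities	precursor_note
AI	ACE-inhibition	Various proteins
AL	DPP-IV-inhibition	Various proteins
EI	ACE-inhibition;DPP-IV-inhibition	Various proteins
EL	Antioxidant	Various proteins
EY	ACE-inhibition;DPP-IV-inhibition	Various proteins
FVPH	Antioxidant	α and β subunits of phaseolins
GI	ACE-inhibition;DPP-IV-inhibition	Various proteins
GL	ACE-inhibition;DPP-IV-inhibition	Various proteins
IA	ACE-inhibition;DPP-IV-inhibition	Various proteins
IE	ACE-inhibition	Various proteins
IH	DPP-IV-inhibition	Various proteins
II	DPP-IV-inhibition	Various proteins
IL	ACE-inhibition;DPP-IV-inhibition	Various proteins
IP	ACE-inhibition;DPP-IV-inhibition	Various proteins
IY	ACE-inhibition	Various proteins
LA	ACE-inhibition;DPP-IV-inhibition	Various proteins
LH	DPP-IV-inhibition	Various proteins
LI	DPP-IV-inhibition	Various proteins
LKA	ACE-inhibition	Various proteins
LL	ACE-inhibition;DPP-IV-inhibition	Various proteins
LP	DPP-IV-inhibition	Various proteins
LPQ	DPP-IV-inhibition	α and β subunits of phaseolins
LT	DPP-IV-inhibition	Various proteins
LY	ACE-inhibition	Various proteins
MI	DPP-IV-inhibition	Various proteins
ML	DPP-IV-inhibition	Various proteins
PR	ACE-inhibition	Various proteins
TI	DPP-IV-inhibition	Various proteins
TL	DPP-IV-inhibition	Various proteins
VAV	ACE-inhibition	Various proteins
VF	ACE-inhibition;DPP-IV-inhibition	Various proteins
VI	DPP-IV-inhibition	Various proteins
VL	DPP-IV-inhibition	Various proteins
VM	DPP-IV-inhibition	Various proteins
VR	ACE-inhibition;DPP-IV-inhibition	Various proteins
VV	DPP-IV-inhibition	Various proteins
YR	DPP-IV-inhibition	Various proteins
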
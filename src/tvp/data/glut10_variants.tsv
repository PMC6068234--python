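variant	label	maf
A106S	benign	0.003
A206T	benign	0.101
A385G	benign	0.013
L475F	benign	0.012
R132W	pathogenic
S81R	pathogenic
G142V	pathogenic
R231Q	pathogenic
R231H	pathogenic
G246E	pathogenic
G426W	pathogenic
E437K	pathogenic
G445E	pathogenic
R105C	pathogenic
E48K	vus
L85P	vus
R132Q	vus
F168L	vus
R225H	vus
R231W	vus
Q243K	vus
S476F	vus
G489R	vus
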
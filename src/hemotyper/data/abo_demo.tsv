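#system=ABO
#gene=ABO
#assembly=hg19
#ref=G,C,G
#reference_row=O02
Phenotype	Chr9:136132908	Chr9:136131650	Chr9:136131414
A101	GG	C	G
A102	GG	T	G
O02	G	C	G
B101	GG	C	A
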
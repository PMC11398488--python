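# Eukaryotic codon:anticodon decoding pairs with selective constraints s
# s=0 Watson-Crick; G:U 0.41; I:C 0.28; I:A 0.9999; U:G 0.68; ATG Watson-Crick only
codon	anticodon	s
AAA	TTT	0
AAA	ATT	0.9999
AAC	GTT	0
AAC	ATT	0.28
AAG	CTT	0
AAG	TTT	0.68
AAT	ATT	0
AAT	GTT	0.41
ACA	TGT	0
ACA	AGT	0.9999
ACC	GGT	0
ACC	AGT	0.28
ACG	CGT	0
ACG	TGT	0.68
ACT	AGT	0
ACT	GGT	0.41
AGA	TCT	0
AGA	ACT	0.9999
AGC	GCT	0
AGC	ACT	0.28
AGG	CCT	0
AGG	TCT	0.68
AGT	ACT	0
AGT	GCT	0.41
ATA	TAT	0
ATA	AAT	0.9999
ATC	GAT	0
ATC	AAT	0.28
ATG	CAT	0
ATT	AAT	0
ATT	GAT	0.41
CAA	TTG	0
CAA	ATG	0.9999
CAC	GTG	0
CAC	ATG	0.28
CAG	CTG	0
CAG	TTG	0.68
CAT	ATG	0
CAT	GTG	0.41
CCA	TGG	0
CCA	AGG	0.9999
CCC	GGG	0
CCC	AGG	0.28
CCG	CGG	0
CCG	TGG	0.68
CCT	AGG	0
CCT	GGG	0.41
CGA	TCG	0
CGA	ACG	0.9999
CGC	GCG	0
CGC	ACG	0.28
CGG	CCG	0
CGG	TCG	0.68
CGT	ACG	0
CGT	GCG	0.41
CTA	TAG	0
CTA	AAG	0.9999
CTC	GAG	0
CTC	AAG	0.28
CTG	CAG	0
CTG	TAG	0.68
CTT	AAG	0
CTT	GAG	0.41
GAA	TTC	0
GAA	ATC	0.9999
GAC	GTC	0
GAC	ATC	0.28
GAG	CTC	0
GAG	TTC	0.68
GAT	ATC	0
GAT	GTC	0.41
GCA	TGC	0
GCA	AGC	0.9999
GCC	GGC	0
GCC	AGC	0.28
GCG	CGC	0
GCG	TGC	0.68
GCT	AGC	0
GCT	GGC	0.41
GGA	TCC	0
GGA	ACC	0.9999
GGC	GCC	0
GGC	ACC	0.28
GGG	CCC	0
GGG	TCC	0.68
GGT	ACC	0
GGT	GCC	0.41
GTA	TAC	0
GTA	AAC	0.9999
GTC	GAC	0
GTC	AAC	0.28
GTG	CAC	0
GTG	TAC	0.68
GTT	AAC	0
GTT	GAC	0.41
TAC	GTA	0
TAC	ATA	0.28
TAT	ATA	0
TAT	GTA	0.41
TCA	TGA	0
TCA	AGA	0.9999
TCC	GGA	0
TCC	AGA	0.28
TCG	CGA	0
TCG	TGA	0.68
TCT	AGA	0
TCT	GGA	0.41
TGC	GCA	0
TGC	ACA	0.28
TGG	CCA	0
TGG	TCA	0.68
TGT	ACA	0
TGT	GCA	0.41
TTA	TAA	0
TTA	AAA	0.9999
TTC	GAA	0
TTC	AAA	0.28
TTG	CAA	0
TTG	TAA	0.68
TTT	AAA	0
TTT	GAA	0.41
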
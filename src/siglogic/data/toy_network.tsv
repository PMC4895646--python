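# Illustrative growth-factor / stress signaling cascade (synthetic toy
# network; not a reconstruction of any published map).  Receptors EGFR and
# TNFR and the DNADamage stimulus are input nodes; activation weight 0.7,
# inhibition weight 0.8.
#! nodes: EGFR TNFR DNADamage RAS PI3K AKT RAF MEK ERK JNK p53 Casp8 Apoptosis Proliferation
#! inputs: EGFR TNFR DNADamage
EGFR	+	0.7	RAS
EGFR	+	0.7	PI3K
RAS	+	0.7	RAF
RAF	+	0.7	MEK
MEK	+	0.7	ERK
PI3K	+	0.7	AKT
TNFR	+	0.7	JNK
TNFR	+	0.7	Casp8
DNADamage	+	0.7	p53
JNK	+	0.7	p53
p53	+	0.7	Apoptosis
Casp8	+	0.7	Apoptosis
AKT	-	0.8	Apoptosis
ERK	+	0.7	Proliferation
p53	-	0.8	Proliferation
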
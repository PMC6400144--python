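# Worked-example evidence table: carp candidate receptors expressed in
# unstimulated macrophages (criterion 2) with per-stimulus regulation flags
# (criterion 3; crd = curdlan, mg = MacroGard). Parenthesised values belong
# to the tetraploid paralogue sharing the row.
description	accession	ctld	itam	tm	rpkm	crd	mg	cypcar
zgc:174904	NP_001170922.1	1	0	1	836		X	00031274
Asialoglycoprotein receptor 1-like isoform 1	XP_026096377.1	2	1	1	654	X	X	00032252
Mannose receptor c type 1	ALS87701.1	2	2 (6)	0	467 (354)			00046879, (00034006)
Asialoglycoprotein receptor 1-like isoform X2	XP_026098956.1	1	0	1	239	X	X	00032253
Ladderlectin-like	XP_026129733.1	1	0	0	215			00046054
C-type lectin domain family 4 member E-like	XP_026087308.1	1	0	1	200			00044344
C-type lectin domain family 4 member C	NP_001313501.1	1	1	1	165		X	00024225
Macrophage mannose receptor 1-like	XP_026142830.1	2 (5)	1 (7)	1	92 (60)		X	00047225, (00023855)
CD209 antigen	XP_003197805.3	1	0	0	83			00049168
C-type lectin domain family 4 member E	XP_002660626.3	1	0	0	60			00014657
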
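# Worked-example evidence table: carp candidate receptors carrying a WxH
# signature inside their CTLD (criterion 1). Parenthesised values belong to
# the tetraploid paralogue sharing the row; the paralogue inherits every
# column it does not override.
description	accession	ctld	itam	tm	rpkm	cypcar
CD248 molecule, endosialin A precursor	NP_001092698.3	1	2	1	0.00	00001997
C type lectin receptor A	NP_001117051.1	1	3 (4)	1	0.45 (0.00)	00016746, (00029396)
Aggrecan	BAJ61837.1	1	3	0	0.00	00023554
Novel protein with Lectin C-type domains precursor	NP_001093528.1	3	2	0	0.01	00031652
Novel protein similar to lectins	CAI21223.1	1 (2)	1	0	0.00	00037242, (00037243)
Collectin 12	BAU33575.1	1	2	1	0.12	00040460
C-type mannose receptor 2-like	XP_026052210.1	3 (1)	1 (4)	0	0.02 (0.00)	00041550, (00047187)
Secretory phospholipase A2 receptor-like	XP_026074237.1	2	1	0	0.00	00045110
C-type lectin 1	AEH76769.1	1	1	1	6.67	00046286
Macrophage mannose receptor 1-like	XP_026074235.1	2	1	1	0.00	00048442
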
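# E. coli K-12 tRNA gene copy numbers by anticodon, compiled from the
# standard K-12 tRNA gene complement (85 genes; the single selenocysteine
# gene selC, anticodon TCA = stop complement, is excluded by construction).
# Reconstructed reference table, not a database export: counts reflect the
# canonical K-12 gene set (e.g. alaT/U/V + alaW/X, argQ/V/Y/Z, metT/U
# elongators + metV/W/Y/Z initiators + ileX pooled under CAT).
genome_id	anticodon	gcn
Eco_K12	GGC	2
Eco_K12	TGC	3
Eco_K12	ACG	4
Eco_K12	CCG	1
Eco_K12	CCT	1
Eco_K12	TCT	1
Eco_K12	GTT	4
Eco_K12	GTC	3
Eco_K12	GCA	1
Eco_K12	CTG	2
Eco_K12	TTG	2
Eco_K12	TTC	4
Eco_K12	CCC	1
Eco_K12	GCC	4
Eco_K12	TCC	1
Eco_K12	GTG	1
Eco_K12	GAT	3
Eco_K12	CAT	7
Eco_K12	CAA	1
Eco_K12	CAG	4
Eco_K12	GAG	1
Eco_K12	TAA	1
Eco_K12	TAG	1
Eco_K12	TTT	6
Eco_K12	GAA	2
Eco_K12	CGG	1
Eco_K12	GGG	2
Eco_K12	TGG	1
Eco_K12	CGA	1
Eco_K12	GCT	1
Eco_K12	GGA	2
Eco_K12	TGA	1
Eco_K12	CGT	1
Eco_K12	GGT	2
Eco_K12	TGT	1
Eco_K12	CCA	1
Eco_K12	GTA	3
Eco_K12	GAC	2
Eco_K12	TAC	5
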
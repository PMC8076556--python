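name	chain	pattern	v_genes	j_gene	partner_v_genes
R-motif	beta	ASS.R.TDTQY	TRBV7-2|TRBV7-3	TRBJ2-3
Extended R-motif	beta	ASS.R.*	TRBV7-2|TRBV7-3	TRBJ2-3
NDYKLS	alpha	I.NDYKLS	TRAV26-1	TRAJ20
Paired R-motif	paired	ASS.R.TDTQY	TRBV7-2|TRBV7-3	TRBJ2-3	TRAV26-1
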
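# Literature-reported SPR dissociation constants and isoelectric points for the
# MBP-targeting octapeptides. kd/sigma_kd carry explicit units. "CBE" = signal
# observed but K_D could not be estimated; "No binding" = no valuable signal.
# Reference values — never regenerated by this package.
peptide	sequence	kd	sigma_kd	pi
MBP-1	SPAGGQDF	4200 uM	1400 uM	3.80
MBP-2	WGTNGGTR	CBE		9.75
MBP-3	APRGGNTS	1500 uM	200 uM	9.79
MBP-4	PQYPPHDN	CBE		5.08
MBP-5	GLPKPGGN	CBE		8.75
MBP-6	PQKGGMWD	1300 uM	500 uM	6.26
MBP-7	WSPNFWWR	CBE		9.75
MBP-8	WHPRPVWE	200 uM	5 uM	6.75
MBP-9	YHFPYFRF	72 uM	3 uM	8.60
MBP-10	YGDGYFRF	No binding		5.83
MBP-11	YHDGYFRF	No binding		6.74
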
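# Literature-reported average docking scores (kcal/mol) for the 13 MBP-targeting
# octapeptide candidates. "vina" = single docking protocol (10 runs x 9 poses);
# "mc_vina" = mutation-off MC rescoring (last 10 configurations of 10 runs).
# "open" = maltose-free open receptor (binding site), "closed" = maltose-bound
# closed receptor (negative-control site). sd columns are standard deviations
# over all samples. Reference values — never regenerated by this package.
peptide	sequence	vina_open_mean	vina_open_sd	mc_vina_open_mean	mc_vina_open_sd	mc_vina_closed_mean	mc_vina_closed_sd
MBP-1	SPAGGQDF	-7.8	0.6	-14.7	1.6	-11.8	0.9
MBP-2	WGTNGGTR	-7.7	0.5	-14.1	1.4	-12.1	1.3
MBP-3	APRGGNTS	-7.0	0.6	-13.8	1.2	-11.5	0.6
MBP-4	PQYPPHDN	-8.0	0.6	-15.1	1.0	-11.1	1.3
MBP-5	GLPKPGGN	-6.6	0.3	-12.5	0.5	-10.3	0.7
MBP-6	PQKGGMWD	-7.1	0.4	-14.9	1.3	-10.7	0.9
MBP-7	WSPNFWWR	-8.3	0.6	-16.8	1.5	-11.9	1.5
MBP-8	WHPRPVWE	-8.3	0.3	-14.8	1.1	-10.1	1.7
MBP-9	YHFPYFRF	-8.9	0.7	-18.7	1.1	-10.5	2.5
MBP-10	YGDGYFRF	-8.1	0.4	-15.1	1.4	-12.6	2.0
MBP-11	YHDGYFRF	-8.1	0.5	-16.2	2.4	-11.8	1.7
poliALA	AAAAAAAA	-7.1	0.3	-11.0	1.0	-9.3	0.5
NEG	AAARRAAA	-6.9	0.4	-13.3	1.1	-11.5	1.6
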
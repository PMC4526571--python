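# pocketsim v0.1.0
# params: lig_a=SBX lig_b=SBX max=8.0 min=3.5 step=0.5 threshold=0.5 tol=0.5
# input pdb_a: site0.pdb sha256:e20e748e2bd1af46
# input pdb_b: site1.pdb sha256:8ac9fb45c6070aa3
cutoff_A	score	n_res_a	n_res_b	similar
3.5	0.2962962962962963	5	7	false
4	0.5502645502645502	7	7	true
4.5	0.6428571428571429	8	8	true
5	0.5339506172839507	8	9	true
5.5	0.4444444444444444	8	10	false
6	0.38585858585858585	8	11	false
6.5	0.4121212121212121	9	11	false
7	0.4158249158249158	11	12	false
7.5	0.4158249158249158	11	12	false
8	0.4225589225589226	12	12	false
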
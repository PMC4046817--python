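# SYNTHETIC example binding-energy matrix for an Lrp-family box motif.
# Penalties (kT relative to consensus) are invented for demonstration and
# testing; only the consensus word (TTGCAAAATTTGCAA) and the consensus K_D
# anchor correspond to published magnitudes for this motif family.
# kd_consensus	6.3e-08
pos	A	C	G	T
1	1.2	1.6	1.8	0.0
2	1.5	2.0	2.2	0.0
3	2.6	2.2	0.0	2.4
4	2.0	0.0	2.8	1.4
5	0.0	1.8	1.2	0.4
6	0.0	1.5	1.0	0.35
7	0.0	1.3	1.1	0.3
8	0.0	1.2	0.9	0.45
9	0.5	1.1	1.3	0.0
10	0.6	1.4	1.2	0.0
11	0.4	1.3	1.5	0.0
12	2.4	2.0	0.0	2.2
13	1.9	0.0	2.6	1.5
14	0.0	1.7	1.1	0.5
15	0.0	1.6	1.2	0.55
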
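# Characterized 15-bp operator-box words of the Ss-LrpB system.
# 'consensus' is the palindromic family consensus; the two Box 1 variants
# are the high-affinity operator box of the Ss-lrpB control region and its
# near-identical counterpart in the Sso0049 promoter (one substitution at a
# less critical position).
name	sequence
consensus	TTGCAAAATTTGCAA
lrpB_operator_box1	TTGTAATTTTTACAA
sso0049_box1	TTGTAATTTTTTCAA
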
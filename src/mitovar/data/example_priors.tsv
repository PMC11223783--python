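# Example per-position allele-frequency prior table (synthetic values,
# illustrating the format: pos, then frequencies for A, C, G, T).
pos	A	C	G	T
73	0.42	0.0	0.58	0.0
146	0.0	0.11	0.0	0.89
152	0.0	0.23	0.0	0.77
263	0.07	0.0	0.93	0.0
750	0.02	0.0	0.98	0.0
1438	0.03	0.0	0.97	0.0
2706	0.25	0.0	0.75	0.0
4769	0.04	0.0	0.96	0.0
7028	0.0	0.35	0.0	0.65
8860	0.03	0.0	0.97	0.0
15326	0.02	0.0	0.98	0.0
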
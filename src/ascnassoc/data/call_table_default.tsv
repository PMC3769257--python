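state	AA	AB	BB	missing
NULL	0.03	0.04	0.03	0.90
A	0.995	0.0	0.0	0.005
B	0.0	0.0	0.995	0.005
AA	0.995	0.0	0.0	0.005
AB	0.0	0.995	0.0	0.005
BB	0.0	0.0	0.995	0.005
AAA	0.35	0.0	0.0	0.65
AAB	0.15	0.25	0.0	0.60
ABB	0.0	0.20	0.10	0.70
BBB	0.0	0.0	0.35	0.65
AAAA	0.30	0.0	0.0	0.70
AAAB	0.20	0.15	0.0	0.65
AABB	0.05	0.25	0.05	0.65
ABBB	0.0	0.10	0.15	0.75
BBBB	0.0	0.0	0.30	0.70
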
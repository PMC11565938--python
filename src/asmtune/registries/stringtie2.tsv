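# StringTie2 v2.2.1 tunable parameters: name, default, kind
name	default	kind	warmup_step
t	0	binary
u	0	binary
m	200	integer
a	10	integer
g	50	integer
j	1	float
f	0.01	float
M	1	float
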
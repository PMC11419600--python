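pre_id	post_id
pATEN1	AMG1
pATEN1	AMG2
pATEN1	AMG3
pATEN1	AMG4
pATEN1	AMG5
pATEN1	AMG6
pATEN1	AMG7
pr1	100
pr1	116
pr-a	116
pr-b	127
Ant1	134
Ant1	135
Ant2	142
Ant2	60
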
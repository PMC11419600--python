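neuron_id	cell_class	VGLUT	VGAT
pATEN1	pATEN	+	0
pr1	PR (I)	+	0
pr-a	PR (II)	0	+
pr-b	PR (II)	+	+
Ant1	Antenna	+	0
Ant2	Antenna	+	0
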
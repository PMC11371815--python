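sample_id	batch	group
S01	b1	0
S02	b1	1
S03	b1	0
S04	b1	1
S05	b1	0
S06	b1	1
S07	b2	0
S08	b2	1
S09	b2	0
S10	b2	1
S11	b2	0
S12	b2	1
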
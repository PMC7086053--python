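s1	p1
s2	p1
s3	p1
s4	p1
s5	p1
s6	p2
s7	p2
s8	p2
s9	p2
s10	p2
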
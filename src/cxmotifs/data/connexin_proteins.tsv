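gene_name	protein_name
A1	CX43
A3	CX46
A4	CX37
A5	CX40
A8	CX50
A9	CX59
A10	CX62
B1	CX32
B2	CX26
B3	CX31
B4	CX30.3
B5	CX31.1
B6	CX30
B7	CX25
C1	CX45
C2	CX47
C3	CX30.2
D2	CX36
D3	CX31.9
D4	CX40.1
E1	CX23
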
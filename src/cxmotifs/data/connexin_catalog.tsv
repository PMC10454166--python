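gene_name	protein_name	domain	anchor	peptide	printed_noncanonical	conserved_in_rat
A1	CX43	CT	230	YVFF	False	True
A1	CX43	CT	265	YAYF	False	True
A1	CX43	CT	286	YKLV	False	True
A4	CX37	CT	266	YLPV	False	True
A4	CX37	CT	281	YNGL	False	True
A8	CX50	CT	266	YQLL	False	True
A8	CX50	CT	278	YFPL	False	True
A8	CX50	CT	316	YQETL	True	True
A8	CX50	CT	323	YAQV	False	True
A9	CX59	CT	283	DYNLL	True	True
A9	CX59	CT	284	YNLL	False	True
A9	CX59	CT	297	YPSL	False	True
A9	CX59	CT	500	LTNNLI	True	True
A10	CX62	CT	433	LSRLL	True	True
A10	CX62	CT	513	YVCV	False	True
B4	CX30.3	IL	117	YDNL	False	True
C1	CX45	IL	141	YPEM	False	True
C1	CX45	CT	301	YTEL	False	True
C2	CX47	CT	330	YSLV	False	True
D2	CX36	IL	109	YSTV	False	True
E1	CX23	CT	200	YFPF	False	False
B1	CX32	IL	103	EKKMLR	True	True
B1	CX32	CT	247	EINKLL	False	True
B1	CX32	CT	260	LKDILR	True	True
B6	CX30	CT	243	EMNELI	False	True
C3	CX30.2	IL	111	EEETLI	False	False
D3	CX31.9	CT	233	EAQKLL	False	False
A3	CX46	CT	296	DFKLL	True	False
A3	CX46	CT	367	EAGAAPLL	True	False
A5	CX40	IL	105	EKRKLR	True	True
A5	CX40	CT	145	LQGTLL	True	True
B5	CX31.1	CT	245	LSGDLI	True	True
B5	CX31.1	CT	255	DSHPPLL	True	True
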
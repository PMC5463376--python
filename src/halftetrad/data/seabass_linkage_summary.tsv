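linkage_group	n_markers	size_cM	structure
LG1A	45	78.04	ambiguous
LG1B	29	51.30	mono-arm
LG2	30	61.83	mono-arm
LG3	24	22.79	mono-arm
LG4	34	44.10	mono-arm
LG5	38	68.19	ambiguous
LG6	26	55.59	mono-arm
LG7	26	72.31	ambiguous
LG8	31	47.92	ambiguous
LG9	23	46.00	ambiguous
LG10	30	34.68	mono-arm
LG11	42	54.26	mono-arm
LG12	29	47.25	mono-arm
LG13	27	54.03	ambiguous
LG14	31	66.67	bi-arm
LG15	37	61.31	mono-arm
LG16	37	49.89	mono-arm
LG17	45	55.03	bi-arm
LG18-21	15	30.23	mono-arm
LG19	30	56.96	mono-arm
LG20	46	45.82	mono-arm
LG22-25	39	62.70	mono-arm
LG24	19	39.07	bi-arm
LGX	31	45.05	assembly-artefact
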
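# Named domain series: maximal runs of blocks belonging to one domain class,
# as catalogued for the four plant AGO clades (plant set) and for the
# cross-kingdom comparison groups (cross-kingdom set).
# "note" flags rows whose running-text rendition disagrees with the tabulated form.
name	domain_class	blocks	set	note
A-1	A	24-13-17	plant
A-2	A	24-28-13-14-17	plant
A-3	A	35-24-20-13-14-17	plant
A-4	A	35-24-20-41-13-34-14-17	plant	block 41 is absent from the text's list of domain-A members
A-5	A	20-13-14-17	cross-kingdom
A-6	A	24-20-13-14-17	cross-kingdom
A-7	A	43-35-24-13-14-23-17	cross-kingdom
A-8	A	43-24-20	cross-kingdom
B-1	B	12-9-44	plant
B-2	B	12-9-30-32	plant
B-3	B	12-9-19	plant
B-4	B	36-12-49-9-19	plant
B-5	B	12-9	cross-kingdom
DUF1785-1	DUF1785	27-6	plant
DUF1785-2	DUF1785	27-33-6	plant
DUF1785-3	DUF1785	33-6	plant
DUF1785-4	DUF1785	27-33	cross-kingdom
PAZ-1	PAZ	18-23-15-11	plant
PAZ-2	PAZ	29-18-15-12-22	plant
PAZ-3	PAZ	29-18-23-15-11-22	plant
PAZ-4	PAZ	18-11-22	cross-kingdom
PAZ-5	PAZ	15-12	cross-kingdom
PIWI-1	PIWI	26-10-7-3-4-21-5-8-1-2	plant	running text prints the same series with "21-58" as a typographic fusion of 21-5-8
PIWI-2	PIWI	26-10-7-40-3-4-21-5-8-1-2-31	plant	running text omits block 1
PIWI-3	PIWI	26-10-7-40-3-4-47-21-5-39-1-2-3	plant	running text inserts block 8 between 5 and 39
PIWI-4	PIWI	26-10-7-3-4-21-5-8-1-2-31	cross-kingdom
PIWI-5	PIWI	10-7-3-4-21-5-8-1-2-31	cross-kingdom
PIWI-6	PIWI	7-3-4-21-5-8-1-2-31	cross-kingdom
PIWI-7	PIWI	10-4-21-5-8-2-1	cross-kingdom
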
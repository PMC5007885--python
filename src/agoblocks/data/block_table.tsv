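# Consensus sequence blocks of the plant ARGONAUTE family (50 blocks).
# domain_tag "-" marks blocks without an assigned canonical-domain component.
block_id	length	consensus	domain_tag	comment
1	50	GNIPPGTVVDTKICHPTEFDFYLCSHAGMQGTSRPTHYHVLWDENNFTAD	PIWI
2	33	ELQTLTNNLCYTYARCTRSVSIVPPAYYAHLAA	PIWI
3	25	PTIIFGMDVTHPHPGEDSSPSIAAV	PIWI
4	26	DWPEVTKYAALVCAQAHRQEMIQDLF	PIWI
5	24	DGVSEGQFYQVLNYELDAIRKACA	PIWI
6	27	GFYQSFRPTQMGLSLNIDMSTTMFIEP	DUF1785
7	29	KMNDQYLANVALKINAKMGGRNTVLVDAL	PIWI
8	21	NWQPPVTFIVVQKRHHTRLFP	PIWI
9	27	PQNGQWNMMNKKMVNGGTVERWACINF	-
10	18	YGDWKWICETDLGIVTQC	PIWI
11	21	RPNYLPMELCKIVEGQRYTKR	PAZ
12	29	YAKEFGISISEKMTQVEARVLPAPWLKYH	-
13	15	AYDGRKSLYTAGPLP	-
14	27	FKVEIKFAAKADMHHLAQFLAGRQADA	-
15	21	VEYFWEMYGYTIQHTHWPCLQ	PAZ
16	15	LPALHENVKNVMFYC	-
17	15	QEALQVLDIVLREHP	-
18	17	DWVKIKKALKNVKVEVT	PAZ
19	50	NVQESVARGFCHELAQMCQISGMEFNPEPVIPIYSARPDQVEKALKHVYH	-
20	29	PDKDLHHYDVTITPEVTSRGVNRAIMAEL	-
21	15	RKATGQKPQRIIFYR	PIWI
22	16	QITALLKMTCQRPQER	PAZ
23	29	NMNQKYRITGLTEQPCRELWFPMDDKNTM	PAZ
24	15	GTKCILKANHFFVEF	-
25	15	GTVDGGMIRELLISF	PIWI
26	15	ELQLLICILPDNNGS	PIWI
27	15	WRCCPVGRSFFSPDM	DUF1785
28	29	FYHYSVALKYEDGRPVDGKGIGRKVIDKV	-
29	15	LPVIDFVAQNLNKDD	PAZ
30	28	SARCDVRHLVRDLIKCGMMKGIMIEPPF	-
31	11	FRARFYMEPEM	PIWI
32	29	FEENPQFRRAPPMVRVEKMFEQIQSKLPG	-
33	11	QDLGGGVEGWR	DUF1785
34	21	FTWKEFEITLVDEDDGTGGPR	-
35	21	QPPPASSKSLRFPLRPGFGTV	-
36	15	DILQTVHHNAYHQDP	-
37	21	YFVNHRNIELRYSGDLPCINV	PAZ
38	29	AQMGQFMKFEDMSETSSSHGGHTSAGAVP	-
39	11	NHNDRNSTDKS	PIWI
40	8	RIPLVSDI	PIWI
41	11	YRESHLGMRLP	-
42	21	GNGSPNESDRKRMRRPYQSKT	PIWI
43	15	GGGRGGGGGGRGGGG	-	also printed as the 11-aa form GRGGGRGRGGR in the running text; the tabulated 15-aa form is authoritative
44	21	FINQLIQRCCQLGIFMNKNTW	-
45	41	SSQRIFHYNVEISPNPSKEVARMIKQKLVEENSAVLSGALP	-
46	21	QNKMEFTVVLEDVSSNRNNGN	-
47	8	KTWQDPQR	PIWI
48	29	SPQFEPTQVLNNVSLLESKLKKIHKAASN	-
49	8	DTGREKDC	-
50	11	TYDSELAGKDF	-
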
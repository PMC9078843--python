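no	classification	delta_mass	frequency	annotation	formula	printed_mass	printed_error
1	Reactive species	15.9949	2872	Oxidation	O	15.9949	0.00
2	Reactive species	31.9899	5965	Dihydroxylation	O(2)	31.9898	1.00e-4
3	Reactive species	3.9953	2029	Trp->Kynurenin	C(-1)O	3.9949	4.00e-4
4	Reactive species	19.9903	45	Trp->Hydroxykynurenin	C(-1)O(2)	19.9998	-9.50e-3
5	Reactive species	115.9754	2	Trp->Hydroxy-bis-tryptophandione then lactoyl	C(3)O(5)	115.9746	8.00e-4
6	Reactive species	354.1708	2	Trp->Hydroxy-bis-tryptophandione then docosahexaenoyl	C(22)H(26)O(4)	354.1831	-1.23e-2
7	Reactive species	368.1698	4	Trp->Hydroxy-bis-tryptophandione then hydroxydecanoyl and histidinyl and replacement of proton with ammonium ion	C(16)H(24)N(4)O(6)	368.1696	2.00e-4
8	Reactive species	432.2146	1	Trp->Hydroxy-bis-tryptophandione then 3-oxocholoyl	C(24)H(32)O(7)	432.2148	-2.00e-4
9	Reactive species	92.0277	1	Nitro-hydroxy-tryptophan then methylation then replacement of proton with ammonium ion	C(1)H(4)N(2)O(3)	92.0222	5.50e-3
10	Reactive species	246.1373	1	Nitro-hydroxy-tryptophan then spermidine adduct and IAA	C(9)H(18)N(4)O(4)	246.1328	4.50e-3
11	Reactive species	312.1545	1	Trihydroxylation and then 3-hydroxy-OPC6	C(12)H(20)N(6)O(4)	312.1546	-1.00e-4
12	Chemical derivative	493.2657	35	Hexosamine and levuglandinyl-lysine lactam adduct	C(26)H(39)NO(8)	493.2676	-1.90e-3
13	Chemical derivative	103.0088	2	Cysteine	C(3)H(5)NOS	103.0092	-4.00e-4
14	AA substitution	-72.9961	22	Trp->Leu/Ile substitution	HC(-5)N(-1)	-72.9953	-8.00e-4
15	AA substitution	-59.0506	16	Trp->His then aspartylurea	C(-6)H(-5)N(-1)O(2)	-59.0524	1.80e-3
16	AA substitution	4.9792	32	Trp->Tyr then formylation	C(-1)H(-1)N(-1)O(2)	4.9790	2.00e-4
17	AA substitution	-13.0308	11	Trp->Cys then corotonaldehyde	C(-4)HN(-1)OS	-13.0283	-2.50e-3
18	AA substitution	32.9748	204	Trp->Asp then benzoyltion	H(-1)N(-1)O(3)	32.9739	9.00e-4
19	AA substitution	88.9942	20	Trp->Thr then citryltion	C(-1)H(3)N(-1)O(7)	88.9848	9.40e-3
20	AA substitution	67.0058	16	Trp->Thr then 3-oxo-5,6-dehydrosuberyl semialdehyde	CH(5)N(-1)O(4)	67.0157	-9.90e-3
21	Artefact	209.0179	76	Carbamidomethylated DTT modification	H(11)C(6)NO(3)S(2)	209.0180	-1.00e-4
22	Unknown	-124.1118	10	Unknown	C(-8)H(-14)N(-1)	-124.1126	8.00e-4
23	Unknown	14.9827	352	Unknown	OH(-1)	14.9871	-4.40e-3
24	Unknown	195.1041	1	Unknown	C(14)H(13)N	195.1048	-7.00e-4
25	Unknown	244.0876	5	Unknown	C(10)H(14)NO(6)	244.0821	5.50e-3
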
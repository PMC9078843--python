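name	composition	class	plausible	source
Trp->Gly substitution	C(-9)H(-7)N(-1)	AA substitution	True	preknown
Trp->Ala substitution	C(-8)H(-5)N(-1)	AA substitution	True	preknown
Trp->Ser substitution	C(-8)H(-5)N(-1)O	AA substitution	True	preknown
Trp->Pro substitution	C(-6)H(-3)N(-1)	AA substitution	True	preknown
Trp->Val substitution	C(-6)H(-1)N(-1)	AA substitution	True	preknown
Trp->Thr substitution	C(-7)H(-3)N(-1)O	AA substitution	True	preknown
Trp->Cys substitution	C(-8)H(-5)N(-1)S	AA substitution	True	preknown
Trp->Asn substitution	C(-7)H(-4)O	AA substitution	True	preknown
Trp->Asp substitution	C(-7)H(-5)N(-1)O(2)	AA substitution	True	preknown
Trp->Gln substitution	C(-6)H(-2)O	AA substitution	True	preknown
Trp->Lys substitution	C(-5)H(2)	AA substitution	True	preknown
Trp->Glu substitution	C(-6)H(-3)N(-1)O(2)	AA substitution	True	preknown
Trp->Met substitution	C(-6)H(-1)N(-1)S	AA substitution	True	preknown
Trp->His substitution	C(-5)H(-3)N	AA substitution	True	preknown
Trp->Phe substitution	C(-2)H(-1)N(-1)	AA substitution	True	preknown
Trp->Arg substitution	C(-5)H(2)N(2)	AA substitution	True	preknown
Trp->Tyr substitution	C(-2)H(-1)N(-1)O	AA substitution	True	preknown
Trp->Leu/Ile substitution	C(-5)HN(-1)	AA substitution	True	preknown
Oxidation	O	Reactive species	True	preknown
Dihydroxylation	O(2)	Reactive species	True	preknown
Trioxidation	O(3)	Reactive species	True	preknown
Trp->Kynurenin	C(-1)O	Reactive species	True	preknown
Trp->Hydroxykynurenin	C(-1)O(2)	Reactive species	True	preknown
Nitration	H(-1)NO(2)	Reactive species	True	preknown
Nitrosylation	H(-1)NO	Reactive species	True	preknown
Didehydro	H(-2)	Reactive species	True	preknown
Trp->Oxolactone	H(-2)O	Reactive species	True	preknown
Trp->Quinone	H(-2)O(2)	Reactive species	True	preknown
Trp->Hydroxy-bis-tryptophandione	H(-4)O(3)	Reactive species	True	preknown
Nitro-hydroxylation	H(-1)NO(3)	Reactive species	True	preknown
Carbamidomethylated DTT	C(6)H(11)NO(3)S(2)	Artefact	True	preknown
Carbamidomethyl	C(2)H(3)NO	Artefact	True	preknown
Dithiothreitol adduct	C(4)H(8)O(2)S(2)	Artefact	True	preknown
Carbamylation	CHNO	Artefact	True	preknown
Glutathionylation	C(10)H(15)N(3)O(6)S	Chemical derivative	True	preknown
Hexose	C(6)H(10)O(5)	Chemical derivative	True	preknown
HexNAc	C(8)H(13)NO(5)	Chemical derivative	True	preknown
Lactoylation	C(3)H(4)O(2)	Chemical derivative	True	preknown
Methylglyoxal adduct	C(3)H(2)O(2)	Chemical derivative	True	preknown
HNE adduct	C(9)H(16)O(2)	Chemical derivative	True	preknown
Phosphorylation	HO(3)P	Chemical derivative	True	preknown
Acetylation	C(2)H(2)O	Chemical derivative	True	preknown
Formylation	CO	Chemical derivative	True	preknown
Methylation	CH(2)	Chemical derivative	True	preknown
Dimethylation	C(2)H(4)	Chemical derivative	True	preknown
Trimethylation	C(3)H(6)	Chemical derivative	True	preknown
Crotonylation	C(4)H(4)O	Chemical derivative	True	preknown
Malonylation	C(3)H(2)O(3)	Chemical derivative	True	preknown
Succinylation	C(4)H(4)O(3)	Chemical derivative	True	preknown
Butyrylation	C(4)H(6)O	Chemical derivative	True	preknown
Propionylation	C(3)H(4)O	Chemical derivative	True	preknown
Glutarylation	C(5)H(6)O(3)	Chemical derivative	True	preknown
Benzoylation	C(7)H(4)O	Chemical derivative	True	preknown
Palmitoylation	C(16)H(30)O	Chemical derivative	True	preknown
Myristoylation	C(14)H(26)O	Chemical derivative	True	preknown
Farnesylation	C(15)H(24)	Chemical derivative	True	preknown
Biotinylation	C(10)H(14)N(2)O(2)S	Chemical derivative	True	preknown
GlyGly (ubiquitin remnant)	C(4)H(6)N(2)O(2)	Chemical derivative	True	preknown
Spermidine adduct	C(7)H(17)N(3)	Chemical derivative	True	preknown
Citrylation	C(6)H(6)O(6)	Chemical derivative	True	preknown
Docosahexaenoylation	C(22)H(30)O	Chemical derivative	True	preknown
Hydroxydecanoylation	C(10)H(18)O(2)	Chemical derivative	True	preknown
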
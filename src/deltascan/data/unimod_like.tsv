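name	composition	class	plausible	source
Oxidation	O	Reactive species	True	unimod
Dioxidation	O(2)	Reactive species	True	unimod
Trioxidation	O(3)	Reactive species	True	unimod
Nitro	H(-1)NO(2)	Reactive species	True	unimod
Nitrosyl	H(-1)NO	Reactive species	True	unimod
Didehydro	H(-2)	Reactive species	True	unimod
Carbonyl	H(-2)O	Reactive species	True	unimod
Methyl	CH(2)	Chemical derivative	True	unimod
Dimethyl	C(2)H(4)	Chemical derivative	True	unimod
Trimethyl	C(3)H(6)	Chemical derivative	True	unimod
Ethyl	C(2)H(4)	Chemical derivative	True	unimod
Acetyl	C(2)H(2)O	Chemical derivative	True	unimod
Formyl	CO	Chemical derivative	True	unimod
Benzoyl	C(7)H(4)O	Chemical derivative	True	unimod
Propionyl	C(3)H(4)O	Chemical derivative	True	unimod
Butyryl	C(4)H(6)O	Chemical derivative	True	unimod
Crotonyl	C(4)H(4)O	Chemical derivative	True	unimod
Crotonaldehyde adduct	C(4)H(6)O	Chemical derivative	True	unimod
Malonyl	C(3)H(2)O(3)	Chemical derivative	True	unimod
Succinyl	C(4)H(4)O(3)	Chemical derivative	True	unimod
Glutaryl	C(5)H(6)O(3)	Chemical derivative	True	unimod
Lactoyl	C(3)H(4)O(2)	Chemical derivative	True	unimod
Citryl	C(6)H(6)O(6)	Chemical derivative	True	unimod
Phospho	HO(3)P	Chemical derivative	True	unimod
Deamidation	H(-1)N(-1)O	Chemical derivative	True	unimod
Amidation	HNO(-1)	Chemical derivative	True	unimod
Carbamyl	CHNO	Artefact	True	unimod
Carbamidomethyl	C(2)H(3)NO	Artefact	True	unimod
Propionamide	C(3)H(5)NO	Artefact	True	unimod
Pyridylethyl	C(7)H(7)N	Chemical derivative	True	unimod
Hexose	C(6)H(10)O(5)	Chemical derivative	True	unimod
HexNAc	C(8)H(13)NO(5)	Chemical derivative	True	unimod
Pentose	C(5)H(8)O(4)	Chemical derivative	True	unimod
Deoxyhexose	C(6)H(10)O(4)	Chemical derivative	True	unimod
Glucuronyl	C(6)H(8)O(6)	Chemical derivative	True	unimod
Palmitoyl	C(16)H(30)O	Chemical derivative	True	unimod
Myristoyl	C(14)H(26)O	Chemical derivative	True	unimod
Octanoyl	C(8)H(14)O	Chemical derivative	True	unimod
Farnesyl	C(15)H(24)	Chemical derivative	True	unimod
Geranylgeranyl	C(20)H(32)	Chemical derivative	True	unimod
Biotinyl	C(10)H(14)N(2)O(2)S	Chemical derivative	True	unimod
Lipoyl	C(8)H(12)OS(2)	Chemical derivative	True	unimod
GlyGly	C(4)H(6)N(2)O(2)	Chemical derivative	True	unimod
Glutathione	C(10)H(15)N(3)O(6)S	Chemical derivative	True	unimod
Cysteinyl	C(3)H(5)NOS	Chemical derivative	True	unimod
Homocysteinyl	C(4)H(7)NOS	Chemical derivative	True	unimod
Methylglyoxal	C(3)H(2)O(2)	Chemical derivative	True	unimod
Glyoxal	C(2)O(2)	Chemical derivative	True	unimod
HNE	C(9)H(16)O(2)	Chemical derivative	True	unimod
4-ONE	C(9)H(12)O(2)	Chemical derivative	True	unimod
MDA adduct	C(3)H(2)O	Chemical derivative	True	unimod
Hydroxydecanoyl	C(10)H(18)O(2)	Chemical derivative	True	unimod
Docosahexaenoyl	C(22)H(30)O	Chemical derivative	True	unimod
Arachidonoyl	C(20)H(30)O	Chemical derivative	True	unimod
Spermidine	C(7)H(17)N(3)	Chemical derivative	True	unimod
Spermine	C(10)H(24)N(4)	Chemical derivative	True	unimod
Putrescine	C(4)H(10)N(2)	Chemical derivative	True	unimod
ADP-ribosyl	C(15)H(21)N(5)O(13)P(2)	Chemical derivative	True	unimod
Phosphoadenosine	C(10)H(12)N(5)O(6)P	Chemical derivative	True	unimod
Dehydration	H(-2)O(-1)	Chemical derivative	True	unimod
Ammonia loss	H(-3)N(-1)	Chemical derivative	True	unimod
Ammonium (proton replacement)	H(3)N	Chemical derivative	True	unimod
Sodium adduct	H(-1)Na	Artefact	True	unimod
Potassium adduct	H(-1)K	Artefact	True	unimod
Iron adduct	H(-2)Fe	Artefact	False	unimod
Calcium adduct	H(-2)Ca	Artefact	False	unimod
Zinc adduct	H(-2)Zn	Artefact	False	unimod
Copper adduct	H(-2)Cu	Artefact	False	unimod
Mercury adduct	H(-1)Hg	Artefact	False	unimod
Selenium replacement	S(-1)Se	Chemical derivative	False	unimod
Chlorination	H(-1)Cl	Reactive species	True	unimod
Dichlorination	H(-2)Cl(2)	Reactive species	True	unimod
Bromination	H(-1)Br	Reactive species	True	unimod
Iodination	H(-1)I	Reactive species	True	unimod
Fluorination	H(-1)F	Reactive species	False	unimod
Hydroxydecanoyl+Histidinyl	C(16)H(25)N(3)O(3)	Chemical derivative	True	unimod
3-oxocholoyl	C(24)H(36)O(4)	Chemical derivative	True	unimod
3-hydroxy-OPC6	C(12)H(20)N(6)O	Chemical derivative	False	unimod
Levuglandinyl-lysine lactam	C(20)H(28)O(3)	Chemical derivative	True	unimod
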
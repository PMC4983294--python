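# Restriction enzyme catalog: commercially available Type IIP endonucleases
# cutting within their recognition site.  Recognition sequences and top-strand
# cut positions (caret notation) transcribed from the public REBASE listing
# (rebase.neb.com, Roberts et al., Nucleic Acids Res; commercial Type II
# subset, accessed 2016 listing).  Degenerate positions use IUPAC codes.
# name	site
AatII	GACGT^C
AccI	GT^MKAC
AclI	AA^CGTT
AfeI	AGC^GCT
AflII	C^TTAAG
AflIII	A^CRYGT
AgeI	A^CCGGT
AluI	AG^CT
ApaI	GGGCC^C
ApaLI	G^TGCAC
ApoI	R^AATTY
AseI	AT^TAAT
AvaI	C^YCGRG
AvaII	G^GWCC
AvrII	C^CTAGG
BamHI	G^GATCC
BanI	G^GYRCC
BclI	T^GATCA
BfuCI	^GATC
BglII	A^GATCT
BspEI	T^CCGGA
BspHI	T^CATGA
BsrGI	T^GTACA
BstBI	TT^CGAA
BstZ17I	GTA^TAC
ClaI	AT^CGAT
CviJI	RG^CY
DdeI	C^TNAG
DraI	TTT^AAA
EagI	C^GGCCG
EcoRI	G^AATTC
EcoRV	GAT^ATC
FspI	TGC^GCA
HaeII	RGCGC^Y
HaeIII	GG^CC
HhaI	GCG^C
HindIII	A^AGCTT
HinfI	G^ANTC
HpaI	GTT^AAC
KpnI	GGTAC^C
MfeI	C^AATTG
MluI	A^CGCGT
MscI	TGG^CCA
MseI	T^TAA
MspI	C^CGG
NaeI	GCC^GGC
NarI	GG^CGCC
NcoI	C^CATGG
NdeI	CA^TATG
NheI	G^CTAGC
NlaIII	CATG^
NotI	GC^GGCCGC
NruI	TCG^CGA
NsiI	ATGCA^T
PciI	A^CATGT
PmlI	CAC^GTG
PstI	CTGCA^G
PvuI	CGAT^CG
PvuII	CAG^CTG
RsaI	GT^AC
SacI	GAGCT^C
SacII	CCGC^GG
SalI	G^TCGAC
Sau96I	G^GNCC
SbfI	CCTGCA^GG
ScaI	AGT^ACT
SfcI	C^TRYAG
SmaI	CCC^GGG
SnaBI	TAC^GTA
SpeI	A^CTAGT
SphI	GCATG^C
Sse9I	^AATT
SspI	AAT^ATT
StuI	AGG^CCT
StyI	C^CWWGG
TaqI	T^CGA
TfiI	G^AWTC
XbaI	T^CTAGA
XhoI	C^TCGAG
XmnI	GAANN^NNTTC
ZraI	GAC^GTC
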
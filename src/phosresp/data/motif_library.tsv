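name	pattern	class	family
xRxSx	xRxSx	ST	basophilic
xKxSx	xKxSx	ST	basophilic
RRxSx	RRxSx	ST	basophilic
KKxSx	KKxSx	ST	basophilic
xRxxSx	xRxxSx	ST	basophilic
RxRxxSx	RxRxxSx	ST	basophilic
KxRxxSx	KxRxxSx	ST	basophilic
xSPx	xSPx	ST	proline_directed
PxSPx	PxSPx	ST	proline_directed
SPxK	SPxK	ST	proline_directed
SPxR	SPxR	ST	proline_directed
SxxE	SxxE	ST	acidophilic
SxxD	SxxD	ST	acidophilic
SDxE	SDxE	ST	acidophilic
SxE	SxE	ST	acidophilic
SxD	SxD	ST	acidophilic
DxxSx	DxxSx	ST	acidophilic
ExxSx	ExxSx	ST	acidophilic
LxRxxSx	LxRxxSx	ST	hydrophobic_directed
LxxSx	LxxSx	ST	hydrophobic_directed
FxxSx	FxxSx	ST	hydrophobic_directed
VxxSx	VxxSx	ST	hydrophobic_directed
MxxSx	MxxSx	ST	hydrophobic_directed
pY	Y	Y	tyrosine
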
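# Small example signed regulatory network (breast-cancer-associated genes).
# Format: source <TAB> effect <TAB> target
ESR1	activation	FOXA1
ESR1	activation	GATA3
ESR1	activation	XBP1
FOXA1	activation	XBP1
FOXA1	activation	ESR1
GATA3	activation	ESR1
MYC	activation	CCND1
MYC	inhibition	CDKN1A
TP53	activation	CDKN1A
TP53	inhibition	BCL2
TP53	activation	BAX
E2F1	activation	CCNE1
E2F1	activation	MYC
RB1	inhibition	E2F1
CCND1	inhibition	RB1
ERBB2	activation	MYC
ERBB2	activation	CCND1
BRCA1	activation	TP53
BRCA1	inhibition	ESR1
AKT1	inhibition	FOXO3
FOXO3	activation	CDKN1B
AKT1	activation	MYC
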
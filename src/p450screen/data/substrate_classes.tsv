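gene	substrate_class
CYP1A1	Drugs
CYP1A2	Drugs
CYP2A6	Drugs
CYP2A13	Drugs
CYP2B6	Drugs
CYP2C8	Drugs
CYP2C9	Drugs
CYP2C18	Drugs
CYP2C19	Drugs
CYP2D6	Drugs
CYP2E1	Drugs
CYP2F1	Drugs
CYP3A4	Drugs
CYP3A5	Drugs
CYP3A7	Drugs
CYP3A43	Drugs
CYP2J2	FattyAcids
CYP2U1	FattyAcids
CYP4A11	FattyAcids
CYP4B1	FattyAcids
CYP4F11	FattyAcids
CYP4F12	FattyAcids
CYP4F22	FattyAcids
CYP4V2	FattyAcids
CYP4F2	Eicosanoids
CYP4F3	Eicosanoids
CYP4F8	Eicosanoids
CYP5A1	Eicosanoids
CYP8A1	Eicosanoids
CYP2R1	Vitamins
CYP24A1	Vitamins
CYP26A1	Vitamins
CYP26B1	Vitamins
CYP26C1	Vitamins
CYP27B1	Vitamins
CYP27C1	Vitamins
CYP1B1	Sterols
CYP7A1	Sterols
CYP7B1	Sterols
CYP8B1	Sterols
CYP11A1	Sterols
CYP11B1	Sterols
CYP11B2	Sterols
CYP17A1	Sterols
CYP19A1	Sterols
CYP21A2	Sterols
CYP27A1	Sterols
CYP39A1	Sterols
CYP46A1	Sterols
CYP51A1	Sterols
CYP2A7	Unknown
CYP2S1	Unknown
CYP2W1	Unknown
CYP4A22	Unknown
CYP4X1	Unknown
CYP4Z1	Unknown
CYP20A1	Unknown
AdR	RedoxPartner
Adx	RedoxPartner
POR	RedoxPartner
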
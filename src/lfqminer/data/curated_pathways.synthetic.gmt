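R-HSA-77111	Synthesis of ketone bodies [synthetic placeholder membership]	HMGCS2	HMGCL	BDH1	ACAT1	OXCT1	HMGCS1	BDH2	HMGCLL1
R-HSA-191273	Cholesterol biosynthesis [synthetic placeholder membership]	HMGCR	HMGCS1	MVK	PMVK	MVD	IDI1	FDPS	FDFT1	SQLE	LSS	CYP51A1	DHCR7	DHCR24	EBP	SC5D	MSMO1	NSDHL	HSD17B7	TM7SF2	LBR
R-HSA-77289	Mitochondrial fatty acid beta-oxidation [synthetic placeholder membership]	ACADM	ACADL	ACADS	ACADVL	HADHA	HADHB	ECHS1	ECI1	ECI2	ACAA2	CPT1A	CPT2	SLC25A20	ETFA	ETFB
R-HSA-390918	Peroxisomal lipid metabolism [synthetic placeholder membership]	ACOX1	ACOX2	ACOX3	EHHADH	HSD17B4	ACAA1	SCP2	CROT	ABCD1	ABCD3	AMACR	PHYH	HACL1	CAT
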
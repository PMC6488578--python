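# Experimentally characterized NES peptides and consensus-matching non-binders
# columns: name	nes_class	start	sequence	phi_local	kd_nM	binder	consensus_fit	engineered	expect_scan
# phi_local: 1-based positions (within the peptide) of the hydrophobic registry
# residues as annotated, including Phi0 when annotated; kd_nM NA = no binding
# detected by pull-down assay; expect_scan = 1 when the scanner is expected to
# recover exactly this class/registry from the peptide sequence alone.
MVM_NS2	1a	77	STVDEMTKKFGTLTIHD	3,6,10,13,15	2	1	1	0	1
superPKI	1a	34	NLNELALKLAGLDINK	2,5,9,12,14	4	1	1	1	1
PKI	1a	34	NSNELALKLAGLDINK	5,9,12,14	34	1	1	0	1
ADAR1	1a	121	RGVDCLSSHFQELSIYQ	3,6,10,13,15	69	1	1	0	1
MEK1	1a	28	TNLEALQKKLEELELDE	3,6,10,13,15	70	1	1	0	1
Pax	1a	264	RELDELMASLSDFKFMA	3,6,10,13,15	700	1	1	0	1
CPEB4-R	1a	395	RMIDILSSELSHMDFTR	3,6,10,13,15	710	1	1	1	1
NPMmutA	1a	278	MTDQEAIQDLCLAVEEVSLRK	7,10,14,17,19	790	1	1	1	1
HDAC5	1a	1081	EAETVSAMALLSVG	4,8,11,13	1600	1	1	0	1
p73	1a	364	NFEILMKLKESLELMELVP	5,8,12,15,17	2000	1	1	0	1
hRio2-R	1a	405	GKIEELAQNFETMEFSR	3,6,10,13,15	2600	1	1	1	1
Strada	1a	413	GIFGLVTNLEELEVD	2,5,9,12,14	10300	1	1	0	1
FMRP-1b	1b	0	YLKEVDQLRALERLQID	5,8,11,14,16	3000	1	1	0	1
SNUPN	1c	1	MEELSQALASSFSVSQDLNS	1,4,8,12,14	12500	1	1	0	1
HPV_E7	1c	73	HVDIRTLEDLLMGTLGIVC	4,7,11,15,17	34000	1	1	0	1
HIV_Rev	2	73	LQLPPLERLTLDC	3,4,6,9,11	1180	1	1	0	0
FMRP	2	424	LKEVDQLRLERLQID	4,7,9,12,14	2000	1	1	0	1
SMAD4	2	134	ERVVSPGIDLSGLTLQ	8,10,13,15	4600	1	1	0	1
mDia2	3	1157	SVPEVEALLARLRAL	5,8,12,15	1600	1	1	0	1
CDC7	3	456	QDLRKLCERLRGMDSSTP	3,6,10,13	20000	1	1	0	1
X11L2	4	55	SSLQELVQQFEALPGDLV	3,6,10,13,17	1500	1	1	0	1
CPEB4	1a-R	379	RTFDMHSLESSLIDIMR	3,5,8,12,15	800	1	1	0	1
hRio2	1a-R	389	RSFEMTEFNQALEEIKG	3,5,8,12,15	2800	1	1	0	1
PKImut1	NA	34	NSNELALKLAGLDANK	5,9,12	150000	1	0	1	0
PKImut2	NA	34	NSNELALKAAGADINK	5,14	900000	1	0	1	0
APC	1a	163	AQLQNLTKRIDSLPL	3,6,10,13,15	NA	0	0	0	0
CyclinD1	1a	281	VDLACTPTDVRDVDI	3,6,10,13,15	NA	0	1	0	1
APRIL	1b	106	LEPLKKLECLKSLDL	4,7,10,13,15	NA	0	1	0	1
hTERT	1c	965	KAGRNMRRKLFGVLRLKC	6,10,14,16	NA	0	1	0	1
DcpS	1c	136	TEKHLQKYLRQDLRL	5,9,13,15	NA	0	1	0	1
Cdk5	2	133	LINRNGELKLADFGL	8,10,13,15	NA	0	1	0	1
FGF1	2	138	THYGQKAILFLPLPV	8,10,13,15	NA	0	0	0	0
COMMD1	3	171	ILKTLSEVEESISTL	5,8,12,15	NA	0	1	0	1
DEAF1	1a-R	452	SWLYLEEMVNSLLNTAQQ	3,5,8,12	NA	0	1	0	1
SGN5	1a-R	221	YALEVSYFKSSLDRKLL	3,5,8,12	NA	0	1	0	1
COMMD1-2	1a-R	164	DEVKVNQILKTLSEVEES	3,5,8,12,15	NA	0	0	0	0
ELF3	1a-R	111	RLVFGPLGDQLHAQLR	2,4,7,11	NA	0	0	0	0
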
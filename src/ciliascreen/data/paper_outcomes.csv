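gene,category,reagent_id,reagent_class,round,phenotype,knockdown
,,scr-1,SCRAMBLED_CONTROL,1,none,
,,scr-2,SCRAMBLED_CONTROL,1,none,
IFT88,CONTROL,siIFT88-1,POSITIVE_CONTROL,1,loss,yes
PCM1,CONTROL,siPCM1-1,POSITIVE_CONTROL,1,anchor,yes
CEP63,DISC1_INTERACTOR,siCEP63-1,SIRNA,1,loss,yes
CEP63,DISC1_INTERACTOR,siCEP63-2,SIRNA,1,loss,yes
FEZ1,DISC1_INTERACTOR,siFEZ1-1,SIRNA,1,loss,yes
FEZ1,DISC1_INTERACTOR,siFEZ1-2,SIRNA,1,loss,yes
PDE4B,DISC1_INTERACTOR,siPDE4B-1,SIRNA,1,loss,yes
PDE4B,DISC1_INTERACTOR,siPDE4B-2,SIRNA,1,loss,yes
SYNE1,DISC1_INTERACTOR,siSYNE1-1,SIRNA,1,loss,yes
SYNE1,DISC1_INTERACTOR,siSYNE1-2,SIRNA,1,none,no
SYNE1,DISC1_INTERACTOR,siSYNE1-3,SIRNA,2,loss,yes
SYNE1,DISC1_INTERACTOR,siSYNE1-4,SIRNA,2,loss,yes
CEP170,DISC1_INTERACTOR,siCEP170-1,SIRNA,1,loss,yes
CEP170,DISC1_INTERACTOR,siCEP170-2,SIRNA,1,none,no
CEP170,DISC1_INTERACTOR,siCEP170-3,SIRNA,2,none,
CEP170,DISC1_INTERACTOR,siCEP170-4,SIRNA,2,none,
ASPM,RARE_VARIANT,siASPM-1,SIRNA,1,loss,yes
ASPM,RARE_VARIANT,siASPM-2,SIRNA,1,loss,yes
CHD4,RARE_VARIANT,siCHD4-1,SIRNA,1,loss,yes
CHD4,RARE_VARIANT,siCHD4-2,SIRNA,1,loss,yes
CHD5,RARE_VARIANT,siCHD5-1,SIRNA,1,loss,yes
CHD5,RARE_VARIANT,siCHD5-2,SIRNA,1,loss,yes
CHD7,RARE_VARIANT,siCHD7-1,SIRNA,1,loss,yes
CHD7,RARE_VARIANT,siCHD7-2,SIRNA,1,loss,yes
KATNAL2,RARE_VARIANT,siKATNAL2-1,SIRNA,1,loss,yes
KATNAL2,RARE_VARIANT,siKATNAL2-2,SIRNA,1,loss,yes
NRXN1,RARE_VARIANT,siNRXN1-1,SIRNA,1,loss,yes
NRXN1,RARE_VARIANT,siNRXN1-2,SIRNA,1,loss,yes
GNB1L,RARE_VARIANT,siGNB1L-1,SIRNA,1,loss,yes
GNB1L,RARE_VARIANT,siGNB1L-2,SIRNA,1,none,no
GNB1L,RARE_VARIANT,siGNB1L-3,SIRNA,2,loss,yes
GNB1L,RARE_VARIANT,siGNB1L-4,SIRNA,2,loss,yes
TBX1,RARE_VARIANT,siTBX1-1,SIRNA,1,loss,yes
TBX1,RARE_VARIANT,siTBX1-2,SIRNA,1,none,no
TBX1,RARE_VARIANT,siTBX1-3,SIRNA,2,loss,yes
TBX1,RARE_VARIANT,siTBX1-4,SIRNA,2,loss,yes
CCDC18,RARE_VARIANT,siCCDC18-1,SIRNA,1,gain,yes
CCDC18,RARE_VARIANT,siCCDC18-2,SIRNA,1,gain,yes
FOXP1,RARE_VARIANT,siFOXP1-1,SIRNA,1,gain,yes
FOXP1,RARE_VARIANT,siFOXP1-2,SIRNA,1,gain,yes
ABCA13,RARE_VARIANT,siABCA13-1,SIRNA,1,none,
ABCA13,RARE_VARIANT,siABCA13-2,SIRNA,1,none,
CHD1,RARE_VARIANT,siCHD1-1,SIRNA,1,none,
CHD1,RARE_VARIANT,siCHD1-2,SIRNA,1,none,
CHD3,RARE_VARIANT,siCHD3-1,SIRNA,1,none,
CHD3,RARE_VARIANT,siCHD3-2,SIRNA,1,none,
CNTN4,RARE_VARIANT,siCNTN4-1,SIRNA,1,none,
CNTN4,RARE_VARIANT,siCNTN4-2,SIRNA,1,none,
CNTNAP2,RARE_VARIANT,siCNTNAP2-1,SIRNA,1,none,
CNTNAP2,RARE_VARIANT,siCNTNAP2-2,SIRNA,1,none,
KIF17,RARE_VARIANT,siKIF17-1,SIRNA,1,none,
KIF17,RARE_VARIANT,siKIF17-2,SIRNA,1,none,
ANK3,COMMON_VARIANT,siANK3-1,SIRNA,1,loss,yes
ANK3,COMMON_VARIANT,siANK3-2,SIRNA,1,loss,yes
CCDC68,COMMON_VARIANT,siCCDC68-1,SIRNA,1,loss,yes
CCDC68,COMMON_VARIANT,siCCDC68-2,SIRNA,1,loss,yes
NEK4,COMMON_VARIANT,siNEK4-1,SIRNA,1,loss,yes
NEK4,COMMON_VARIANT,siNEK4-2,SIRNA,1,loss,yes
NOTCH4,COMMON_VARIANT,siNOTCH4-1,SIRNA,1,loss,yes
NOTCH4,COMMON_VARIANT,siNOTCH4-2,SIRNA,1,loss,yes
NT5C2,COMMON_VARIANT,siNT5C2-1,SIRNA,1,loss,yes
NT5C2,COMMON_VARIANT,siNT5C2-2,SIRNA,1,loss,yes
SDCCAG8,COMMON_VARIANT,siSDCCAG8-1,SIRNA,1,loss,yes
SDCCAG8,COMMON_VARIANT,siSDCCAG8-2,SIRNA,1,loss,yes
TCF4,COMMON_VARIANT,siTCF4-1,SIRNA,1,loss,yes
TCF4,COMMON_VARIANT,siTCF4-2,SIRNA,1,loss,yes
TRANK1,COMMON_VARIANT,siTRANK1-1,SIRNA,1,loss,yes
TRANK1,COMMON_VARIANT,siTRANK1-2,SIRNA,1,loss,yes
MIR137,COMMON_VARIANT,MIR137-mimic-1,MIRNA_MIMIC,1,gain,yes
MIR137,COMMON_VARIANT,MIR137-mimic-2,MIRNA_MIMIC,1,gain,yes
CACNA1C,COMMON_VARIANT,siCACNA1C-1,SIRNA,1,none,
CACNA1C,COMMON_VARIANT,siCACNA1C-2,SIRNA,1,none,
CNNM2,COMMON_VARIANT,siCNNM2-1,SIRNA,1,none,
CNNM2,COMMON_VARIANT,siCNNM2-2,SIRNA,1,none,
CSMD1,COMMON_VARIANT,siCSMD1-1,SIRNA,1,none,
CSMD1,COMMON_VARIANT,siCSMD1-2,SIRNA,1,none,
HISTH2BJ,COMMON_VARIANT,siHISTH2BJ-1,SIRNA,1,none,
HISTH2BJ,COMMON_VARIANT,siHISTH2BJ-2,SIRNA,1,none,
MMP16,COMMON_VARIANT,siMMP16-1,SIRNA,1,none,
MMP16,COMMON_VARIANT,siMMP16-2,SIRNA,1,none,
NRGN,COMMON_VARIANT,siNRGN-1,SIRNA,1,none,
NRGN,COMMON_VARIANT,siNRGN-2,SIRNA,1,none,
ODZ4,COMMON_VARIANT,siODZ4-1,SIRNA,1,none,
ODZ4,COMMON_VARIANT,siODZ4-2,SIRNA,1,none,
PGBD1,COMMON_VARIANT,siPGBD1-1,SIRNA,1,none,
PGBD1,COMMON_VARIANT,siPGBD1-2,SIRNA,1,none,
PRSS16,COMMON_VARIANT,siPRSS16-1,SIRNA,1,none,
PRSS16,COMMON_VARIANT,siPRSS16-2,SIRNA,1,none,
STT3A,COMMON_VARIANT,siSTT3A-1,SIRNA,1,none,
STT3A,COMMON_VARIANT,siSTT3A-2,SIRNA,1,none,
TRIM26,COMMON_VARIANT,siTRIM26-1,SIRNA,1,none,
TRIM26,COMMON_VARIANT,siTRIM26-2,SIRNA,1,none,
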
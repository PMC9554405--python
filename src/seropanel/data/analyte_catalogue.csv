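group,target,uniprot,gene,symbol
1,Cytokine,P09919,CSF3,G-CSF
1,Cytokine,P04141,CSF2,GM-CSF
1,Chemokine,P09341,CXCL1,CXCL1/Gro alpha
1,Growth/regulatory factor,P14210,HGF,HGF
1,Cytokine,P48551,IFNAR2,IFN alpha
1,Cytokine,P01579,IFNG,IFN gamma
1,Cytokine,P01583,IL1A,IL-1alpha
1,Cytokine,P01584,IL1B,IL-1beta
1,Cytokine,P60568,IL2,IL-2
1,Soluble receptor,P31785,IL2RG,sIL-2R
1,Cytokine,P08700,IL3,IL-3
1,Cytokine,P05112,IL4,IL-4
1,Cytokine,P05113,IL5,IL-5
1,Cytokine,P05231,IL6,IL-6
1,Cytokine,P13232,IL7,IL-7
1,Cytokine,P10145,CXCL8,IL-8
1,Cytokine,P15248,IL9,IL-9
1,Cytokine,P22301,IL10,IL-10
1,Cytokine,P29460/P29459,IL12B/IL12A,IL-12p70
1,Cytokine,P35225,IL13,IL-13
1,Cytokine,P40933,IL15,IL-15
1,Cytokine,Q14005,IL16,IL-16
1,Cytokine,Q16552,IL17A,IL-17A
1,Cytokine,Q14116,IL18,IL-18
1,Cytokine,Q9NYY1,IL20,IL-20
1,Cytokine,Q9HBE4,IL21,IL-21
1,Cytokine,Q9GZX6,IL22,IL-22
1,Cytokine,Q9NPF7,IL23A,IL-23
1,Cytokine,Q8NEV9,IL27,IL-27
1,Cytokine,Q6EBC2,IL31,IL-31
1,Chemokine,P02778,CXCL10,CXCL10/IP-10
1,Chemokine,O14625,CXCL11,CXCL11/I-TAC
1,Cytokine,P15018,LIF,LIF
1,Chemokine,P13500,CCL2,CCL2/MCP-1
1,Chemokine,P80075,CCL8,CCL8/MCP-2
1,Chemokine,P80098,CCL7,CCL7/MCP-3
1,Cytokine,P09603,CSF1,M-CSF
1,Chemokine,O00626,CCL22,CCL22/MDC
1,Cytokine,P14174,MIF,MIF
1,Chemokine,Q07325,CXCL9,CXCL9/MIG
1,Chemokine,P10147,CCL3,CCL3/MIP-1alpha
1,Chemokine,P13236,CCL4,CCL4/MIP-1beta
1,Chemokine,P78556,CCL20,CCL20/MIP-3alpha
1,Growth/regulatory factor,P03956,MMP1,MMP-1
1,Growth/regulatory factor,P21583,KITLG,SCF
1,Chemokine,P48061,CXCL12,CXCL12/SDF-1alpha
1,Cytokine,P01375,TNF,TNF-alpha
1,Cytokine,P01374,LTA,TNF-beta
1,Soluble receptor,P20333,TNFRSF1B,sTNF-R2
1,Soluble receptor,O14798,TNFRSF10C,sTRAIL
1,Cytokine,Q969D9,TSLP,TSLP
1,Chemokine,O43927,CXCL13,CXCL13/BLC
1,Growth/regulatory factor,P01138,NGF,beta-NGF
1,Soluble receptor,P28908,TNFRSF8,sCD30
1,Soluble receptor,P29965,CD40LG,sCD40L
1,Chemokine,P42830,CXCL5,CXCL5/ENA-78
1,Chemokine,P51671,CCL11,CCL11/Eotaxin
1,Chemokine,O00175,CCL24,CCL24/Eotaxin-2
1,Chemokine,Q9Y258,CCL26,CCL26/Eotaxin-3
1,Growth/regulatory factor,P09038,FGF2,FGF-2
1,Chemokine,P78423,CX3CL1,CX3CL1/Fractalkine
1,Growth/regulatory factor,P15692,VEGFA,VEGF-A
1,Soluble receptor,O75888,TNFSF13,sAPRIL
1,Soluble receptor,Q9Y275,TNFSF13B,sBAFF/sBLYS
1,Soluble receptor,O43508,TNFSF12,sTWEAK
2,Immune checkpoint LT,Q9Y5U5,TNFRSF18,sGITR
2,Immune checkpoint LT,O43557,TNFSF14,sHVEM
2,Immune checkpoint LT,P10747,CD28,sCD28
2,Immune checkpoint LT,P33681,CD80,sCD80/sB7-1
2,Immune checkpoint LT,Q07011,TNFRSF9,s4-1BB/sCD137
2,Immune checkpoint LT,P26842,CD27,sCD27
2,Immune checkpoint LT,P16410,CTLA4,sCD152/sCTLA4
2,Immune checkpoint LT,Q15116,PDCD1,sPD1
2,Immune checkpoint LT,Q9NZQ7,CD274,sPD-L1
2,Immune checkpoint LT,Q9BQ51,PDCD1LG2,sPD-L2
2,Immune checkpoint LT,P14902,IDO1,sIDO
2,Immune checkpoint LT,Q7Z6A9,BTLA,sBTLA
2,Immune checkpoint LT,P18627,LAG-3,sLAG-3
2,Immune checkpoint LT,Q8TDQ0,HAVCR2,sTIM-3
2,Immune checkpoint LT,P23510,TNFSF4,sCD134/sOX40
2,Immune checkpoint LT,Q5ZPR3,CD276,sCD276/sB7-H3
2,Immune checkpoint LT,Q08722,CD47,sCD47/sIAP
2,Immune checkpoint LT,P09326,CD48,sCD48/sBLAST-1
2,Immune checkpoint LT,O00182,LGALS9,sGalectin-9
2,Immune checkpoint LT,O75144,ICOSLG,sICOS Ligand/sB7-H2
2,Immune checkpoint LT,Q96H15,TIMD4,sTIMD-4
2,Immune checkpoint LT,Q9H7M9,VSIR,sVISTA/sB7-H5
3,Immune checkpoint NK,Q29983,MICA,sMICA
3,Immune checkpoint NK,Q29980,MICB,sMICB
3,Immune checkpoint NK,Q9BZM6,ULBP1,sULBP-1
3,Immune checkpoint NK,Q9BZM4,ULBP3,sULBP-3
3,Immune checkpoint NK,Q8TD07,RAET1E,sULBP-4
3,Immune checkpoint NK,P40200,CD96,sCD96/sTactile
3,Immune checkpoint NK,P15151,PVR,sCD155/sPVR
3,Immune checkpoint NK,Q92692,NECTIN2,sCD112/sNectin-2
3,Immune checkpoint NK,P21589,NT5E,sCD73/sNT5E
3,Immune checkpoint NK,P05089,ARG1,sArginase-1
3,Immune checkpoint NK,Q9Y286,SIGLEC7,sSiglec-7
3,Immune checkpoint NK,Q9Y336,SIGLEC9,sSiglec-9
3,Immune checkpoint NK,P14222,PRF1,sPerforin
3,Immune checkpoint NK,P12830,CDH1,sE-Cadherin
3,Immune checkpoint NK,Q68D85,NCR3LG1,sB7-H6
3,Immune checkpoint NK,P05109,S100A8,sS100A8
3,Immune checkpoint NK,P06702,S100A9,sS100A9
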
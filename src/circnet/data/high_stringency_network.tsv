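circ_id	mirna_id	n_binding_sites	target_genes
X:47431299-48327824	hsa-miR-139-5p	6	NOTCH1;STAMBP;TPD52
8:144989320-145838888	hsa-miR-320a	2	METTL7A;PBX3;PLS1;SEC14L1;VCL;VIM;VOPP1;YPEL2
8:144989320-145838888	hsa-miR-320b	2	RTKN;VCL;VOPP1
X:47431299-48327824	hsa-miR-449a	1	BAZ2A;MFSD8;NOTCH1;TSN;ZNF551
8:144989320-145838888	hsa-miR-125a-3p	1	ANKRD62;C15orf40;COL18A1;MFSD11;MPEG1;MUL1;TTC31;WDR12;ZNF641
X:47431299-48327824	hsa-miR-125a-5p	1	CD34;MEGF9;PANX1;RIT1;TP53INP1
8:144989320-145838888	hsa-miR-125a-5p	1	CD34;MEGF9;PANX1;RIT1;TP53INP1
X:47431299-48327824	hsa-miR-324-5p	1	FOXO1;MEMO1;PSMD4;SMARCD2
14:23815526-24037279	hsa-miR-142-3p	1	BTBD7;CLDN12;CPEB2;CSRP2;DAG1;KIF5B;PTPN23;WHAMM
4:88394487-89061166	hsa-miR-133b	1	FAM160B1
4:88394487-89061166	hsa-miR-448	1	DDIT4;PURG
4:88394487-89061166	hsa-miR-339-5p	1	AXL;HLA-E;METTL7A;ZNF285;ZNRF3
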
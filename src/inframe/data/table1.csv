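variant_id,gene,hgvs_c,hgvs_p,template,structural,clinical,ddig_in,sift_indel,provean
FSCN2:c.1071_1073del,FSCN2,c.1071_1073del,p.(Lys357del),human FSCN1 (pdb 1DFC),unlikely,unlikely,D,D,D
RP2:c.260_268del,RP2,c.260_268del,p.(Thr87_Cys89del),human RP2 (pdb 2BX6),probably,possibly,D,D,D
RPE65:c.1443_1445del,RPE65,c.1443_1445del,p.(Glu481del),cow RPE65 (pdb 3FSN),unclear,probably,D,D,D
BFSP2:c.697_699del,BFSP2,c.697_699del,p.(Glu233del),human vimentin (pdb 3UF1),probably,probably,D,D,D
CRYBA1:c.272_274del,CRYBA1,c.272_274del,p.(Gly91del),human CRYBA4 (pdb 3LWK),probably,probably,D,D,D
CRYBA4:c.136_156del,CRYBA4,c.136_156del,p.(Ser46_Gly52del),human CRYBA4 (pdb 3LWK),probably,probably,D,D,D
CRYGC:c.61_63del,CRYGC,c.61_63del,p.(Thr21del),human CRYGB (pdb 2JDF),unclear,probably,D,D,D
PITX2:c.429_431del,PITX2,c.429_431del,p.(Arg144del),human PITX2 (pdb 2LKX),probably,probably,N,D,D
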
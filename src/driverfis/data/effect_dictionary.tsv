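# MAF Variant_Classification -> mutation effect class
# effects: silent | nonsilent | noncoding | null
Silent	silent
Synonymous	silent
Missense_Mutation	nonsilent
Missense	nonsilent
In_Frame_Del	nonsilent
In_Frame_Ins	nonsilent
Stop_Codon_Del	nonsilent
Stop_Codon_Ins	nonsilent
Start_Codon_SNP	nonsilent
Nonsense_Mutation	null
Nonstop_Mutation	null
Frame_Shift_Del	null
Frame_Shift_Ins	null
Splice_Site	null
Splice_Region	null
Translation_Start_Site	null
Start_Codon_Del	null
Start_Codon_Ins	null
De_novo_Start_OutOfFrame	null
3'UTR	noncoding
5'UTR	noncoding
3'Flank	noncoding
5'Flank	noncoding
Intron	noncoding
IGR	noncoding
RNA	noncoding
lincRNA	noncoding
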
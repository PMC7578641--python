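symmetric_difference
n_base_pairs
gc_content
length_bp_ratio
seq_length
central_loop_length
free_energy_per_nt
bulge_number
tail_length
n_tails
triplet_(((_A
triplet_(((_C
triplet_(((_G
triplet_(((_U
triplet_((._A
triplet_((._C
triplet_((._G
triplet_((._U
triplet_(.._A
triplet_(.._C
triplet_(.._G
triplet_(.._U
triplet_(.(_A
triplet_(.(_C
triplet_(.(_G
triplet_(.(_U
triplet_.((_A
triplet_.((_C
triplet_.((_G
triplet_.((_U
triplet_.(._A
triplet_.(._C
triplet_.(._G
triplet_.(._U
triplet_..(_A
triplet_..(_C
triplet_..(_G
triplet_..(_U
triplet_..._A
triplet_..._C
triplet_..._G
triplet_..._U
kmer_A
kmer_C
kmer_G
kmer_U
kmer_AA
kmer_AC
kmer_AG
kmer_AU
kmer_CA
kmer_CC
kmer_CG
kmer_CU
kmer_GA
kmer_GC
kmer_GG
kmer_GU
kmer_UA
kmer_UC
kmer_UG
kmer_UU
kmer_AAA
kmer_AAC
kmer_AAG
kmer_AAU
kmer_ACA
kmer_ACC
kmer_ACG
kmer_ACU
kmer_AGA
kmer_AGC
kmer_AGG
kmer_AGU
kmer_AUA
kmer_AUC
kmer_AUG
kmer_AUU
kmer_CAA
kmer_CAC
kmer_CAG
kmer_CAU
kmer_CCA
kmer_CCC
kmer_CCG
kmer_CCU
kmer_CGA
kmer_CGC
kmer_CGG
kmer_CGU
kmer_CUA
kmer_CUC
kmer_CUG
kmer_CUU
kmer_GAA
kmer_GAC
kmer_GAG
kmer_GAU
kmer_GCA
kmer_GCC
kmer_GCG
kmer_GCU
kmer_GGA
kmer_GGC
kmer_GGG
kmer_GGU
kmer_GUA
kmer_GUC
kmer_GUG
kmer_GUU
kmer_UAA
kmer_UAC
kmer_UAG
kmer_UAU
kmer_UCA
kmer_UCC
kmer_UCG
kmer_UCU
kmer_UGA
kmer_UGC
kmer_UGG
kmer_UGU
kmer_UUA
kmer_UUC
kmer_UUG
kmer_UUU
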
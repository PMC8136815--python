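# Example RBP motif compendium (illustrative, compiled from widely used
# consensus elements in the splicing literature; IUPAC degenerate DNA,
# U written as T).  One row per pattern; repeated names merge into one motif.
RBFOX	TGCATG
QKI	ACTAAY
RBPMS	CACACTA
PTBP1	TCTTC
NOVA	YCAYYCAY
MBNL1	YGCTGY
CELF1	TGTGTG
TIA1	TTTTTT
HNRNPC	TTTTT
HNRNPA1	TAGGGT
SRSF1	GGAGGA
SRSF2	GGNGT
TRA2B	GAAGAA
ELAVL1	TTTRTTT
KHDRBS1	ATAAAA
U2AF2	TTTTCC
ESRP2	TGGGRA
HNRNPF	GGGAG
HNRNPL	ACACA
SRSF7	ACGACG
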
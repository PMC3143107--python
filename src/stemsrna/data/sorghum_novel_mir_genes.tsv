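mir_gene	chrom	start	end	strand	mature_size	mature_seq	star_seq	star_size	genbank
sbi-MIR5381	Ch1	574388	574497	+	19	AAGATCTGTGGCGCCGAGC	TCGGCGCTAAGATCTCTGG	19	JN205291
sbi-MIR5382	Ch2	1930828	1930937	+	18	CCAATCTAAACAGGCCCT	GACCTGTTTAGATTGGGA	18	JN205292
sbi-MIR5383	Ch4	43242765	43242874	+	24	ATGACAGAGCTCCGGCAGAGATAT	TTCTCCGCCGAGCTTATCTGTGG	23	JN205293
sbi-MIR5384	Ch4	45785396	45785505	+	18	CGCGCCGCCGTCCAGCGG	CTTGGCCGGTGCACGCGTC	19	JN205294
sbi-MIR5385	Ch6	56307517	56307626	+	22	ACCACCAACCCCACCGCTTCTC	GAAGCGGTGGTGTTGGTGGTGA	22	JN205295
sbi-MIR5386	Ch7	877244	877353	+	20	CGTCGCTGTCGCGCGCGCTG	GGTCAGGGCAGAGCACGCA	19	JN205296
sbi-MIR5387	Ch7	15969322	15969431	+	25	TAACACGAACCGGTGCTAAAGGATC	CCCTTTAGCACCGGTTCGTGTTACA	25	JN205297
sbi-MIR5388	Ch8	1629110	1629219	+	22	ATCTTTGCCGGGTGTCTCTGAC	CAGCAAACATTCGGCAAAGAAAA	23	JN205298
sbi-MIR5389	Ch8	4848342	4848451	+	21	GCTTGAGTTTATCAGCCGAGT	ATGGCTTATCAGCCAAGTGA	20	JN205299
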
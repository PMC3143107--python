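library	n_raw	n_perfect	pct_perfect	n_singlets	pct_singlets	n_clusters	n_nonredundant	pct_nonredundant
Mix	4023513	2547108	63	276044	11	35083	311127	8
BTx623	2115266	1348361	64	169063	12	20056	189119	9
Rio	3173601	2180988	69	234276	11	31563	265839	8
LB/EF F2s	11974953	7472940	62	653279	9	120132	773411	6
HB/LF F2s	17049436	9459548	55	835284	9	164623	999907	6
Total	38336769	23008945	60	2167946	9	371457	2539403	8
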
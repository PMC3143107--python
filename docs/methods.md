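# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic study design does and does not
establish about real data.

## Coordinates and alphabets

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the I/O boundary in both directions. Sequences are held in
the DNA alphabet; U is normalised to T at ingest. SOLiD colors follow the
di-base code (0 = identical, 1 = A↔C/G↔T, 2 = A↔G/C↔T, 3 = A↔T/C↔G),
which is the XOR of the 2-bit base codes; decoding therefore needs only
the primer base and is exact.

## Read mapping

Mapping happens in base space after decoding. Because only perfect
matches are retained downstream, a colorspace-aware aligner adds nothing:
any single color error corrupts all following bases and cannot survive a
perfect-match filter, so the retained read set is identical either way.
The mapper finds the longest prefix (18–25 nt) of the decoded read with
at least one exact genomic hit, using an exact 18-mer index over both
strands (minus-strand entries are keyed by reverse complement and
expressed in plus coordinates). The 25-nt platform read limit means
adapter sequence never enters the insert, so the longest matching prefix
*is* the insert length; the residual ±1-nt ambiguity that arises when the
first adapter base coincidentally extends the genomic match (probability
¼ per read) is documented here but not modelled. Reads matching more than
10 loci report the first 10 in (chrom, start, strand) order and carry a
multimapped flag. Inserts shorter than 18 nt are treated as unmapped;
k below 12 is rejected outright because index collisions explode.

## Clustering and library statistics

Clusters group reads with byte-identical insert sequences (100%
identity); a "cluster" in reports means ≥2 identical reads, singlets are
reported separately, and the non-redundant set is the number of distinct
sequences, so `non_redundant = singlets + clusters` holds by
construction and is asserted at run time. Clustering uses the decoded,
length-trimmed insert rather than the raw 25-color read; identical
inserts give identical prefixes, so this ordering is equivalent and
simpler. Statistics are computed before repeat filtering.

## Element attribution and hotspots

Element attribution is read-centric: each mapped read is assigned the
highest-priority feature kind overlapped by any of its hits, with default
priority MIR > rRNA > tRNA > repeat > exon > intron > gene > other
("other" = intergenic). The priority order is configurable because no
single convention exists for composition plots. Hotspot detection is
locus-centric instead: every reported hit of every 25-nt read contributes
coverage, and a hotspot is a maximal run of bases each covered by
*strictly more than* `min_coverage` reads (default 1000; configurable
since the right threshold scales with sequencing depth). Extending a
reported interval by one base always violates the threshold. Hotspots
are labelled annotated/unannotated by overlap with rRNA/tRNA features —
unannotated ones flag rRNA/tRNA genes missing from the annotation.

## Known-miRNA quantification

A read is counted for (family, mature) when any hit lies on an annotated
mature miRNA's strand with its 5' end within ±2 nt of the annotated 5'
end (star analogously). The tolerance lets species longer than their
annotation count — e.g. a 22-nt read over a 20-nt annotated mature — and
absorbs 5' processing jitter. Multi-mapped reads count once per family,
not once per locus, so paralog-rich families are not inflated; per-gene
counts are additionally reported for arm-usage analysis at gene
granularity.

The expression filter calls a family expressed when it is detected in at
least 3 of the 5 libraries (the Mix participates) and reaches 10 reads
summed over all five. Fold-change analysis normalises family-level
counts (mature + star summed) to reads per million perfect matches and
compares parent 1/parent 2 and bulk 1/bulk 2; a family is called
inherited when both ratios clear the 2-fold cutoff on the same side.
Both strands are summed so that an arm-usage switch alone cannot fake a
fold change in family output. Zero counts produce an explicit
`undetected_in_one` call rather than an infinite ratio — no pseudocount
is added. The Mix library is excluded from fold-change analysis (it is a
mixture, not a genotype). Arm-usage records report mature/star per
library, flag `arm_switch` when star ≥ mature, and leave the ratio
undefined at star = 0.

## De novo miRNA calling

Clusters with ≥5 reads that survived repeat filtering and do not touch
known MIR loci are merged into read loci (gap ≤ 50 nt, so the two arms of
one hairpin share a locus); the most abundant cluster of each locus seeds
two 110-nt windows placing the read 20 nt from the 5' and 3' window edge
respectively. Excising per locus rather than per cluster is what
miRDeep-style pipelines do and avoids folding hundreds of redundant
windows over deep rRNA/tRNA fragment loci; the final
dedupe-overlapping-windows step makes the output identical. Windows
clipped by a chromosome end are dropped.

Windows are folded with a Nussinov maximum-base-pairing DP (Watson-Crick
plus G:U, minimum loop 3, O(n³)). The traceback is deterministic:
pairing the leftmost base is preferred whenever it attains the optimum,
with the smallest partner. Max-pairing replaces free-energy folding
deliberately — it needs no external dependency, is exactly testable
against exhaustive enumeration, and the candidate criteria below depend
only on the pairing topology of the stem, which max-pairing recovers for
genuine hairpins.

A candidate passes when all four criteria hold:

* **star geometry** — the star predicted from the structure with 2-nt 3'
  overhangs (partner of mature[-3] → star 5' end, partner of mature[0]
  +2 → star 3' end, ±1-nt tolerance for unpaired ends) lies inside the
  window with ≤2 nt of bulge asymmetry versus the mature length;
* **opposite arms** — mature and star are disjoint and every paired
  duplex position of the mature pairs into the star interval (the 2-nt
  mature overhang is exempt: it is unpaired by definition);
* **duplex quality** — ≤4 unpaired mature positions within the duplex;
* **read signature** — mature + star reads are ≥90% of all window reads
  and ≥75% of mature-arm reads share one 5' end.

These deterministic thresholds stand in for a probabilistic hairpin
score: they are the plant miRNA annotation criteria stated directly, and
failed candidates carry their per-criterion flags for reporting. Called
candidates are re-fed to quantification as new families and pass through
the same expression filter and fold-change analysis.

## Target prediction

Each alignment column is penalised match 0, G:U 0.5, gap 2, other 1, and
the penalty is doubled within the first 13 bases counted from the miRNA
5' end; a transcript qualifies when the best full-miRNA alignment scores
≤ 8. "First 13" counting is by miRNA position by default; counting by
alignment column is available behind a switch in `score_duplex` (the two
differ only when a gap falls before position 13). Gap columns consuming
no miRNA base inherit the boost of the preceding miRNA position (position
1 for a leading gap) — our resolution of a case the scheme leaves
unstated. Site search is an exhaustive semi-global DP (miRNA fully
aligned, free transcript ends, ≤3 gaps) against the reversed transcript —
the antiparallel duplex geometry — run over every transcript with no
heuristic prescreen, so sensitivity is exact by construction. All
non-overlapping sites at or under the threshold are reported best-first.
The predicted cleavage position is the transcript base opposite miRNA
positions 10–11, the canonical slicing register for plant miRNAs; it is
reported for downstream comparison, not validated in silico.

## Synthetic study design

The generator builds a 30-kb single-chromosome genome hosting: two repeat
families × four identical 300-nt copies (so repeat reads genuinely
multimap); eight annotated MIR hairpins (miR172/169/395/160/164/319
expressed, miR399/437 annotated but silent, so the detected/annotated
family ratio is exercised); two unannotated novel hairpins; 100-nt rRNA
and tRNA arrays present in the genome and in the truth record but
*omitted from the emitted GFF3*; and two protein-coding genes with
introns, one of which hosts the miR172-analog hairpin in an intron. The
miR172-analog is annotated 20 nt but sequenced as a 22-nt species from
the same 5' end.

Planted hairpins are stems of the mature against its wobbled reverse
complement (two forced G:U pairs at ~⅓ and ~⅔ of the stem) with a 12-nt
loop, a 2-nt star 3' overhang and random flanks filling a 110-nt window.
The wobbles ensure no ≥18-nt stretch of the mature is perfectly reverse
complemented elsewhere in the window, so mature reads cannot cross-map to
the star arm. A design is accepted only after the package's own folder
recovers ≥90% of the planted stem and the canonical star prediction —
de novo recall is therefore testable by construction. Planted
mature/star sequences are verified unique in the genome (regenerated on
collision).

Library composition per genotype: 75% repeat reads, 10% rRNA/tRNA
fragments (emitted at the 25-nt read limit, emulating truncation of
longer molecules), miRNA families at the planted abundances, remainder
intergenic/genic background. siRNA-like lengths are drawn from a 18–24 nt
distribution with 22 nt dominant, so the library-level size profile shows
the 22-nt and ≥25-nt peaks characteristic of stem tissue. Defaults:
miR172 at 6% of the grain-type library; inherited families (miR169,
miR172 higher in parent 1; miR395 higher in parent 2) planted at 3-fold —
comfortably beyond the 2-fold call threshold, as in the data the design
emulates, so sampling noise at these depths cannot flip a call —
trending-but-not-inherited families (miR160/164/319) at 1.4-fold; bulks
inherit their parent's value for inherited families and sit midway for
the rest. miR395 arm usage is 6:1 mature:star in the grain-type genotype
and bulk 1, 1:1 in the sweet-type genotype and bulk 2; all other families
default to 6:1. Family reads carry a ±1-nt 5' jitter with probability
0.08 and 5% of family reads are random hairpin fragments, so signature
thresholds are exercised away from their trivial values. No sequencing
errors are simulated: the analysis keeps perfect matches only, so errors
would only rescale library depth.

Phenotypes follow a one-major-locus additive model: an F2 genotype g ∈
{0,1,2} (segregating 1:2:1) shifts both Brix (base 5, +4 per allele) and
leaf count (base 8, +3 per allele), plus bivariate Gaussian noise
(sd 1.5 and 1.2, correlation 0.3). Bulk selection takes Brix ≤5 with ≤9
leaves against Brix ≥13 with ≥14 leaves from 553 plants. The Mix library
samples n/4 reads without replacement from each of the four libraries
(earlier libraries absorb the remainder).

Default problem sizes — 30-kb genome, 20,000 reads per library, five
libraries — were chosen so that every planted effect is recovered with
wide statistical margins (≥200 expected reads per inherited family on its
low side; >1000× hotspot coverage) while a full simulate-plus-analysis
cycle stays in the tens of seconds, which makes multi-seed parameter
recovery practical to test routinely.

## What the synthetic design does not show

The generator produces exact-substring reads with uniform base
composition, identical repeat copies, a single chromosome, and planted
hairpins guaranteed foldable by max pairing. Real data add sequencing
error (here removed by the perfect-match filter, at the cost of depth),
diverged repeat copies, isomiR 5'/3' heterogeneity beyond ±1 nt, AT/GC
skew, and hairpins whose true structure a max-pairing folder may
misrepresent. Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated assumptions, not the
sensitivity of the annotation criteria on real libraries. The published
library-scale totals (tens of millions of reads) are not reproducible at
this scale; what is checked against the published record is the internal
arithmetic of its statistics table and the mature/star sequence/size
consistency of its novel MIR table.

## Numerical conventions and edge cases

* Percentages in statistics tables are round-half-even of the exact
  ratio; one published row floor-rounds its singlet share, so cross-table
  checks compare at ±1 there.
* Ratios with zero denominators are never emitted: arm ratios become
  undefined (flagged), fold-change calls become `undetected_in_one`.
* Ties in clustering order resolve by (count desc, sequence); candidate
  dedupe keeps verdict-true candidates first, then best signature.
* All RNG streams derive from one integer seed via numpy's seed-sequence
  mechanism; identical configs give byte-identical outputs.
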
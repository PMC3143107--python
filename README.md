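# stemsrna

Analysis of the small RNA component of plant stem transcriptomes, built
around the study design that compares grain-type and sweet-type sorghum:
two parental genotypes, two bulked-segregant F2 pools selected for stem
sugar (Brix) and flowering time, and an equal-proportion mix of the four,
all sequenced as 25-nt SOLiD colorspace libraries.

The package implements the complete analysis chain as a library plus a CLI:

* **SOLiD colorspace codec** — exact di-base encode/decode (`io_formats`);
* **perfect-match prefix mapping** — decoded reads are mapped by their
  longest 18–25-nt prefix with an exact k-mer index over both strands, at
  most 10 hits reported per read (`mapping`);
* **identical-read clustering** and per-library sequencing statistics
  (singlets, clusters of ≥2 identical reads, non-redundant set)
  (`library_stats`);
* **size/element profiling and 25-nt hotspot detection** — read-length
  histograms, priority-based attribution of reads to genomic elements
  (MIR > rRNA > tRNA > repeat > exon > intron > gene > intergenic), repeat
  filtering, and maximal runs of bases covered by strictly more than 1000
  25-nt reads, flagged by rRNA/tRNA annotation status (`genome_profile`);
* **known-miRNA quantification** — family × strand count matrix with a
  ±2-nt 5'-shift tolerance, the expression filter (detected in ≥3
  libraries and ≥10 reads over the five), reads-per-million fold-change
  analysis between parents and bulks with inheritance calls at a 2-fold
  cutoff, and miR/miR\* arm-usage ratios (`mirna_quant`);
* **rule-based de novo miRNA discovery** — 110-nt window excision around
  deep read clusters, Nussinov maximum-base-pairing folding (Watson-Crick
  + G:U, min loop 3), and explicit annotation criteria: mature/star on
  opposite arms with a 2-nt 3' overhang duplex, ≤4 unpaired mature bases,
  ≤2-nt bulge asymmetry, and a clean read signature (`denovo_mirna`);
* **miRNA target prediction** — exhaustive semi-global DP over every
  transcript with the plant scoring scheme: match 0, G:U 0.5, gap 2,
  mismatch 1, doubled within the first 13 miRNA bases, sites reported at
  total score ≤ 8 (`target_prediction`);
* **a synthetic data generator** (`synthetic_data`) that emulates the
  study: ~75% repeat-derived reads, a dominant 22-nt miR172-analog inside
  a host-gene intron (over a 20-nt annotation), unannotated rRNA/tRNA
  arrays producing ≥25-nt fragments, 3-fold inherited parental expression
  differences, genotype-dependent miR395 arm usage (≈6:1 vs ≈1:1), and an
  F2 phenotype model with bulk selection (Brix ≤5 & ≤9 leaves vs Brix ≥13
  & ≥14 leaves, from 553 plants).

Two small published reference tables ship with the package (`reference`):
the per-library deep-sequencing statistics of the five sorghum stem
libraries and the nine novel sorghum MIR genes (sbi-MIR5381…sbi-MIR5389)
with their mature/star sequences.

## Worked example

```sh
stemsrna simulate --seed 1 --out sim
stemsrna run --data-dir sim --out out
```

`out/` then contains TSV tables for every stage. Highlights from this run:

`novel_mirnas.tsv` — both planted unannotated hairpins are recovered, with
their mature/star duplex and read signature:

```
mir_gene  position           strand  mature_size  mature_seq             star_seq               mature_reads  star_reads  signature
novel-1   chr1: 16088..16197 +       21           ATAGTCGGCATTTCTCCAAAG  TTGGGGAAATGTCGACTATAT  423           68          0.959
novel-2   chr1: 27960..28069 +       21           ATGCTACTAAGCAGTTAAGGT  CTTAGCTGCTTGGTAGCATCG  386           58          0.943
```

`star_ratios.tsv` (miR395 rows) — the planted arm-usage difference between
the grain-type (bc02) and sweet-type (bc03) genotypes is recovered: the
mature:star ratio is ≈4.5:1 in bc02 but ≈0.9:1 in bc03, where the star
strand is as abundant as the mature strand (arm switch flagged):

```
miR395  bc02  152   34  4.4706  False
miR395  bc03  283  308  0.9188  True
```

`fold_changes.tsv` — miR169 and miR172 are called higher in parent 1 with
the difference inherited by its bulk, and miR395 the opposite, at the
2-fold cutoff:

```
family  call               parental_ratio  bulk_ratio
miR169  inherited_high_P1  2.895           2.8579
miR172  inherited_high_P1  2.9457          3.3343
miR395  inherited_high_P2  0.3147          0.3224
```

`hotspots.tsv` — the two planted rRNA/tRNA arrays, absent from the GFF3,
appear as maximal runs of bases covered by >1000 25-nt reads and are
labelled unannotated:

```
chrom  start  end    name       score  mean_coverage  annotated
chr1   20493  20562  hotspot_1  1612   1492.48        unannotated
chr1   26104  26173  hotspot_2  1685   1532.28        unannotated
```

`targets.tsv` — the engineered target transcript is found for novel-2 with
duplex score 1.0 (one mismatch outside the boosted 5' region) and the
predicted cleavage position opposite miRNA positions 10–11:

```
mirna    transcript          start  end  score  cleavage_pos
novel-2  transcript-target1  150    171  1.0    161
```

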
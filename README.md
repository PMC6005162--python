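# loopinv

Hairpin loop-inversion detection, single-event down-weighting and
character-subsampling support experiments for plastid (chloroplast)
alignments.

## The problem

Non-coding chloroplast DNA is rich in short stem-loop (hairpin) structures:
two adjacent reverse-complementary runs (the stem, ≥ 4 bp) flanking an
unpaired loop. The loop — or part of it — can be replaced by its reverse
complement in a single intra-molecular event. In a multiple sequence
alignment such an inversion looks like a dense cluster of substitutions,
and because the same hairpin can flip independently on different branches
(homoplasy), treating every column as an independent character can produce
strongly supported but spurious clades. The remedy is to *down-weight* each
inversion to a single character: keep one column of the inverted segment
and exclude the rest.

`loopinv` implements that workflow for phylogenomic practitioners:

* **detection** — scan the consensus and every distinct row of a gapped
  alignment for stem-loops (seed-and-extend over loop centers, perfect
  Watson–Crick stems, one unpaired "bulge" base allowed after the minimum
  stem), then call a loop inversion wherever reverse-complementing a
  contiguous loop segment of a minority of rows brings it within
  `t_after ≤ 2` substitutions of the majority form while explaining at
  least `min_before = 3` substitutions. Each event reports the pair
  `d_before/d_after`: the Hamming distance of the minority segment to the
  majority before and after reverting;
* **down-weighting** — exclusion plans (one kept column per event) written
  as MrBayes-ready NEXUS `exclude` blocks;
* **subsampling experiments** — K-fold interleaved duplication (site
  patterns ×K, nothing new) and delete-fraction jackknife (retain
  `round(f·L)` columns without replacement, 20 replicates), with
  per-clade, per-replicate support tables and the three support categories
  (most-replicates-high / rarely-high-rarely-contradicted /
  generally-poor);
* **tree backend** — Jukes–Cantor distances, neighbor joining and
  bootstrap supports at desk scale, plus ingestion of externally produced
  newick tree samples (posterior samples) in three support conventions;
* **parsimony mapping** — binary inversion presence/absence characters
  mapped on a fixed rooted topology by exact small parsimony with
  accelerated-transformation (ACCTRAN) resolution, labelling each branch
  gain (0→1) or loss (1→0) relative to the outgroup state;
* **synthetic data** — a seeded generator (JC/HKY along a tree, planted
  hairpins, minority-lineage inversions including homoplasious ones, noisy
  windows) and a packaged 41-taxon fixture embedding the eight published
  stem-loop regions, so the whole pipeline runs with no download.

## Worked example

Generate the packaged fixture and scan it:

```sh
$ loopinv simulate --scenario table2 --outdir demo
41 taxa, L=639 -> demo
$ loopinv scan demo/table2_fixture.fasta --outdir demo/scan
8 inversion events -> demo/scan/events.tsv
```

The event table mirrors the published layout (first rows shown):

```
loop  alignment_coordinates  segment  sequence_majority  sequence_minority  substitutions_before_after  sequences_minority
A     40-61                  49-51    GAA                TTC                3/0   Phalaenopsis,bicolor,concreta7,concreta9,melanantha,tesselata1
B     95-140                 114-123  TTTTTTGAGG         CCTCAAAAAA         8/0   humbertii2,melanantha,oreocharis1,tsinjoarivensis2
C     175-218                192-202  GGGTAAGGCCT        AGGCCTTACCC        7/0   eurychila
D     258-305                275-288  CAAGATGAATATGA     TCATATTCATCTTG     8/0   humbertii1,steudneri
```

Reading row A: at alignment columns 49–51 the majority of taxa carry the
loop `GAA` while six taxa carry `TTC`; the minority differs by 3
substitutions before reverting and 0 after (`TTC` is exactly the reverse
complement of `GAA`), so a single inversion event explains all three
differences. Down-weight the events and re-scan — the events are gone:

```sh
$ loopinv downweight demo/table2_fixture.fasta demo/scan/events.json --outdir demo/dw
excluded 54 columns -> demo/dw/downweighted.nex
$ loopinv scan demo/dw/downweighted_applied.fasta --outdir demo/scan2
0 inversion events -> demo/scan2/events.tsv
```

The same objects are available as a library:

```python
from loopinv import call_inversions, scan_alignment
from loopinv.synthetic import table2_fixture

msa, expected = table2_fixture()
events = call_inversions(msa, scan_alignment(msa))
assert [e.event_id for e in events] == list("ABCDEFGH")
```

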
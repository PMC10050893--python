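# jdint — interface-occupancy analysis for Josephin-domain protein docking

Ataxin-3 is a deubiquitinase whose N-terminal Josephin domain (JD,
residues 1–180) is followed by a flexible C-terminal tail carrying three
ubiquitin-interaction motifs and a polyglutamine (polyQ) tract (residues
292–305, 14Q in the common wild-type form). Expansion of the polyQ tract
(modelled here as 50Q) causes spinocerebellar ataxia type 3, and a central
question is *where* ataxin-3's interaction partners bind and *how* the
expansion changes those interfaces.

`jdint` is a toolkit for analysing panels of protein–protein docking
results against ataxin-3 and its Josephin-domain relatives (JOSD1, JOSD2,
fly Josephin-like). It is aimed at structural bioinformaticians who have
per-interactor docking outputs (HADDOCK-style cluster tables plus
PISA-style per-structure interface reports, or plain interface-residue
lists) and want reproducible, statistically grounded interface maps.

## What it computes

1. **Representative structure selection.** Docking clusters with z-score
   > 0 are discarded; among the rest the structure with the most
   interfacing residues on the reference protein wins, with ties broken by
   total interface contacts, then interface area. Interactors longer than
   1,500 residues are excluded up front.
2. **Artifact filtering.** Interactors with ≥ 6 interface residues inside
   the polyQ tract are flagged as low-confidence predictions and removed.
3. **Occupancy profiles and recognition regions.** For a panel of *n*
   interactors, the occupancy of residue *i* is
   `100 · #{interactors whose interface contains i} / n` (percent).
   Molecular recognition regions are maximal runs of positions with
   occupancy strictly above 50%, chained while successive qualifying
   positions are ≤ 3 apart, and kept only when the span exceeds 3
   residues.
4. **Binding classification.** Each interactor is JD-dominant or
   C-terminal-dominant according to where the majority of its interface
   residues fall relative to residue 180; the class imbalance is tested
   with an exact two-sided sign test.
5. **Wild-type vs expanded comparison.** Interfaces on the two ataxin-3
   forms are paired per interactor through the polyQ coordinate map
   (positions downstream of the tract shift by +36 for a 14Q→50Q
   expansion), paired sign tests are run on total/JD/C-terminal residue
   counts, and the relative strength change `(exp − wt)/wt` is categorised
   as increase/decrease/similar at a strict 10% cutoff.
6. **CDS curation.** A separate module implements the coding-sequence
   filtering protocol used to assemble the gene-family phylogeny input:
   exact-duplicate removal, ±10% size filtering against query lengths,
   collapse of isoform transcripts sharing identical blocks > 250 nt
   (keeping the sequence closest to the reference CDS size), header
   annotation, in-frame stop-codon screening, and terminal stop stripping.

A seeded synthetic-data module generates every input the pipeline
consumes (interface panels with planted recognition regions, paired wt/exp
datasets with C-terminal inflation and planted polyQ artifacts, CDS sets
with planted curation events), so the whole pipeline is testable without
any external downloads.

## Worked example

Generate a synthetic paired wt/exp panel of 100 interactors, call the
wild-type recognition regions, and correlate the two occupancy profiles:

```bash
$ jdint simulate --kind pair --n 100 --seed 7 --out demo
wrote synthetic pair data to demo

$ jdint regions --interfaces demo/interfaces_wt.tsv --reference wt_atxn3 \
      --out demo/regions.bed
region_1        10-18   mean 56.8%
region_2        45-57   mean 57.9%
region_3        80-92   mean 57.8%
region_4        120-127 mean 55.9%
region_5        160-172 mean 56.9%
region_6        210-222 mean 55.8%
region_7        250-262 mean 53.4%
7 region(s)

$ jdint compare --interfaces-a demo/interfaces_wt.tsv \
      --interfaces-b demo/interfaces_exp.tsv \
      --reference-a wt_atxn3 --reference-b exp_atxn3
R = 0.9941  p = 0  y = 1.0149x + 1.1693  n = 347
```

The seven called regions recover the planted ones (five in the JD, two in
the C-terminal tail); region boundaries can be clipped by a residue or two
where sampling noise drops a boundary position below the 50% cutoff. The
profile comparison pairs the 347 positions that map 1:1 between the 14Q
and 50Q coordinate systems (the 14 wild-type polyQ positions have no
counterpart and are dropped); R ≈ 0.99 with a near-unit slope says the
expansion reshapes the interface landscape only modestly — the C-terminal
inflation shows up in the positive intercept and in the paired sign tests
rather than as a change of shape.

The same analyses are available as library functions
(`jdint.compute_occupancy`, `jdint.call_regions`, `jdint.paired_counts`,
`jdint.sign_test`, …) and as a one-shot pipeline
(`jdint run --config config.yaml`) that writes occupancy TSVs, region BED
files, classification and paired-count tables, a stats JSON and a
reproducibility manifest.

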
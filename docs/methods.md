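# Methods

This note documents the models, rules and numerical choices behind
`jdint`, in the order the pipeline applies them.

## Coordinate model

Residue numbering is 1-based with inclusive intervals throughout
("residues 1–180" means 180 residues). The wild-type ataxin-3 annotation
is JD 1–180, UIMs 224–243 / 244–263 / 331–349, polyQ 292–305 (14Q),
length 361. The expanded (50Q) form is derived by extending the polyQ
span to 292–341 and shifting everything downstream by +36 (length 397,
UIM3 367–385). The wt↔exp position map is the identity upstream of the
tract, a +36/−36 offset downstream, and undefined inside the tract — so
any paired analysis silently drops the 14 wild-type (respectively 50
expanded) polyQ positions. JOSD1/JOSD2/JosL annotations ship as editable
defaults (JD 1–180 with plausible lengths); their exact coordinates are
not asserted anywhere because they are user-supplied metadata.

The JD/C-terminal split used for classification and paired counts is
[1, 180] vs [181, length]: the JD is close to half of wild-type ataxin-3,
which makes the two-region sign test a natural paired comparison.

## Docking selection rules

* **z-score filter:** clusters are retained at z ≤ 0; the boundary value
  0 is kept.
* **Representative structure:** maximise reference-chain interfacing
  residues; tie-break on total interface contacts, then interface area,
  then lexicographic structure id. "Total contacts" is read as the count
  of interfacing residues across *all* chains of the complex (otherwise
  the tie-break would duplicate the primary criterion); the final
  id-based tie-break exists purely for reproducibility.
* **Size exclusion:** interactors strictly longer than 1,500 residues are
  excluded (1,500 itself is retained).
* **polyQ artifact filter:** interactors with ≥ 6 interface residues
  inside the polyQ tract are excluded; 5 is retained. In the paired
  analysis the filter runs on each form with its own tract coordinates
  (292–305 wt, 292–341 exp), and failing either form drops the pair —
  the per-form rule is our choice where the protocol is silent.

PISA-style XML is read per `pdb_entry`: a residue is interfacing when its
buried surface area is positive; per-interface areas are summed. The
simplified interface TSV (tab-separated, header required, comma-separated
1-based positions, duplicates ignored, extra columns tolerated) is the
interchange format between all stages.

## Occupancy and recognition regions

Occupancy is a per-position percentage over the interactor panel.
Region calling has three tunables (all in `AnalysisConfig`):

* `occupancy_cutoff` (default 50, **strict** >): with n = 4 interactors a
  position needs at least 3 of them.
* `max_gap` (default 3): successive qualifying positions chain into one
  region while their difference is ≤ 3, i.e. at most two intervening
  non-qualifying residues. "Less than three consecutive residues apart"
  is ambiguous between difference ≤ 3 and ≤ 2; we use ≤ 3 and expose the
  knob.
* `min_region_span` (default 3, region kept when span **exceeds** it):
  "larger than three positions" is read as span ≥ 4, measured on the
  region's full extent rather than its qualifying-position count — the
  two coincide except when gaps sit at region edges, which the chaining
  rule precludes. Setting `min_region_span=0` reproduces the short form
  of the rule (no span filter), which is how the rule is first applied to
  the four-interactor JosL panel.

Classification ties (equal JD and C-terminal counts) get the label `tie`
and are excluded from downstream sign tests, consistent with tie handling
in the paired tests themselves.

## Statistics

* **Sign test:** exact two-sided binomial at p₀ = 0.5, doubled smaller
  tail capped at 1, ties excluded — the convention of common statistical
  packages' exact tests. No normal approximation at any n.
* **Mann–Whitney U:** exact null distribution when both groups have ≤ 12
  observations and the pooled values are tie-free; otherwise the normal
  approximation with midrank tie correction (scipy's implementation
  behind a thin wrapper).
* **Pearson + fit:** correlation with the two-sided t-transform p-value
  and an ordinary least-squares line of y on x, as used for comparing
  occupancy profiles between datasets (human vs fly panels, wt vs exp
  forms). Profile comparison requires ≥ 3 paired positions and drops
  unmapped (polyQ) positions.

Significance is conventionally 5%; no multiple-testing correction is
applied (none is part of the protocol).

## CDS curation

Steps run in protocol order — per-file duplicate removal and ±10% size
filter, merge + re-deduplication, isoform collapse, header annotation,
in-frame stop screening, terminal stop stripping — and the report's
per-step counts telescope, with every removal attributed to exactly one
reason (`duplicate`, `size`, `isoform`, `internal-stop`, `frame`).
Choices worth noting:

* The size filter compares lengths in a single unit (nucleotides here)
  and is inclusive at exactly ±10%.
* Isoform collapse groups sequences sharing an identical block **strictly
  longer** than 250 nt, transitively (A~B and B~C collapse to one
  survivor among the three); the survivor is the sequence closest in
  length to the reference CDS, ties broken by keeping the longer, then by
  accession. Shared blocks are found with a complete 32-mer seed
  prefilter followed by an exact longest-common-substring check
  (`difflib.SequenceMatcher`); the test suite keeps an independent
  quadratic dynamic-programming oracle.
* Stop-codon screening reads frame 1 of the standard genetic code;
  sequences whose length is not a multiple of 3 cannot be scanned and are
  removed with reason `frame`. Terminal-stop stripping is idempotent.

The initial homology search, alignment and tree inference are external
tools and out of scope; the module starts from candidate CDS FASTA.

## Synthetic data

The generators are pure functions of (parameters, seed) via numpy's
`default_rng`.

* **Interface panels:** coverage is sampled independently per position —
  probability `p_in` inside planted regions, `p_out` elsewhere. This is
  the simplest model consistent with the per-residue occupancy statistics
  the pipeline consumes; it does **not** model contiguous interface
  patches, correlated residues, or docking-score structure, so passing
  recovery tests show the calling rules are correct, not that real
  docking noise behaves this way. The default planted layout echoes the
  observed binding architecture: five regions in the JD, two in the
  C-terminal tail, none touching the polyQ tract. Optional class
  structure (`class_mix`) restricts each interactor's high-coverage
  regions to one side of the JD boundary, which is how planted
  JD-dominant/C-terminal-dominant classes are made recoverable.
* **Paired wt/exp panels:** the expanded interface is the
  coordinate-mapped wild-type interface plus C-terminal gains: an
  uncovered C-terminal position enters with probability
  `(cterm_inflation − 1) · p`, so expected C-terminal coverage scales by
  about the inflation factor; gains never occur in the JD (an optional
  `jd_attrition` can thin exp JD coverage, default off). Defaults
  (`p_in` 0.55, `p_out` 0.08) were chosen by closed-form arithmetic over
  the planted layout to emulate realistic interface sizes — about 70
  interfacing residues in total, two thirds of them in the JD — and an
  inflation of 1.3 matches the observed wt→exp C-terminal ratio.
  Non-artifact interactors sample no polyQ positions at all (tract
  contacts are precisely the artifact signal); designated artifact
  interactors get ≥ 6 planted tract contacts in each form, so the filter
  can be validated against exact truth.
* **CDS sets:** clean sequences are random in-frame codon strings within
  ±10% of a query length; planted events are exact duplicates, isoform
  partners embedding a 300-nt block from a host (with a length strictly
  farther from the reference, so the host survives), internal-stop and
  off-size sequences, plus two boundary probes: a pair sharing exactly
  250 nt (flanking bases forced to mismatch, so both survive the strict
  rule) and a sequence of exactly 1.10× a query length (inclusive
  boundary, kept). Ground-truth survivor lists are derived from the
  construction, never from running the pipeline.

## Problem sizes and determinism

The recovery experiments use 40 interactors × 100 seeds for region
recovery, 100 interactors × 50 seeds for the wt/exp directional
experiment, and 5 seeded CDS sets for curation agreement — sizes at which
the binomial noise floor is far from the pass thresholds while the whole
acceptance script runs in seconds. All randomness flows from explicit
seeds; pipeline runs write a manifest (config snapshot, input SHA-256
digests, per-stage counts, version) and re-running a config reproduces
outputs byte-for-byte.

## Known limitations

* The Bernoulli interface model ignores residue contiguity and
  interactor-specific interface sizes; occupancy variance in real docking
  panels is larger at fixed n.
* The Mann–Whitney exact path follows standard exact/midrank conventions;
  other packages' exact implementations may differ in tie handling.
* JOSD1/JOSD2/JosL default annotations are placeholders for user-supplied
  values.
* The pipeline consumes docking outputs; it neither runs docking nor
  judges pose quality beyond the z-score/contact-count rules.
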
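# Methods

## Scope and design

`symbiotag` couples a synthetic multiplexed-amplicon-run generator to the
analysis pipeline it is meant to exercise.  The generator is first-class
code, not a test fixture: its truth table (origin library, observed library,
origin phylotype, switched flag for every read) is what makes the
tag-switching estimator testable at all, since a real run with only one
observable tag per read carries no ground truth.

The pipeline follows the classic pyrotag workflow: exact-barcode
demultiplexing and primer trimming, length/expected-error filtering of the
trimmed insert, pooled dereplication, abundance-sorted greedy centroid
clustering at 99% identity, a libraries × phylotypes table with per-library
major-phylotype calls, the mistag analysis, and a UPGMA host-specificity
check.

## The simulator

### Reference phylotypes

A uniform-random root ITS sequence (default 565 nt; with the 8 nt barcode
and 17 nt forward primer the amplicon is ~590 nt, comfortably above the
400 nt read cap) gives rise to one ancestor per host species, and each
ancestor to that host's phylotypes.  Both divergence parameters are
*expected pairwise divergences* between sister sequences, so each branch
substitutes sites at half the configured rate (uniform choice among the
three other bases).  Defaults: 0.10 between hosts, 0.02 within a host.

Candidate phylotypes are rejected and re-drawn until every cross-phylotype
identity is below `0.99 − margin` (margin 0.003) — both over the full length
and over the first 250 bases, the shortest insert the length filter admits —
so the reference set is separable at the clustering threshold for every
read-length window.  A bounded attempt count turns impossible geometry
(too many phylotypes for too little divergence) into an explicit error.

### Reads, qualities, errors

Each library receives exactly one true phylotype of its host species
(round-robin, so every phylotype is carried by ≥1 library), and a depth
drawn uniformly from 300–3,000 reads.  A read is
`barcode + AAGGTAGCCGTACGAGA + ITS-prefix`, truncated to a length drawn from
N(350, 25) clipped to [200, 400] — always shorter than the amplicon, which
is precisely why the reverse tag is never observed and tag switching is
undetectable read-by-read.

Quality strings decline linearly from Q38 (5′) to Q25 (3′) with per-base
jitter (sd 2), and the substitution probability at each base **is**
`10^(−Q/10)`: the error process is generated from the written qualities, so
expected-error filtering confronts the true error model.
`per_base_error_rate` rescales the profile; its default, 0.001, is the mean
per-base rate the nominal profile implies.  This default is deliberate: with
the study's fixed QC rule (EE ≤ 0.5 on a ~250–375 nt insert) any mean rate
much above ~0.0015 would reject essentially every read, i.e. the QC
threshold itself certifies that retained pyrotag reads have sub-0.15%
per-base error.  Errors hit the barcode and primer too, so a small fraction
of reads (~0.4%) legitimately fails demultiplexing.

### Tag switching

With probability `tag_switch_prob` (default 0.15, the run-level artifact
frequency the analysis is calibrated to) a read's observed barcode is
replaced by one drawn uniformly from the other n−1 libraries.  Under this
convention a switched read is always observed in a foreign library, so the
expected switched fraction in the truth table equals `tag_switch_prob`
exactly; the invariant tests assert the empirical fraction against the
binomial 99% interval.  Switching is applied before sequencing errors (the
switched tag is what gets sequenced).

### What is emulated, and what is not

The generator emulates: skewed library sizes, per-base miscalls coupled to
realistic quality strings, one-observable-tag geometry, host-structured
reference phylogeny, error-free Sanger clone libraries drawn from the
pre-run amplicon pool.  It does **not** emulate flowgram/homopolymer errors,
chimeras, PCR or MDA amplification bias, or barcode-sequence error
correction.  Passing tests therefore show that the pipeline and estimator
behave correctly under a substitution-error, uniform-switching model — not
that real 454 data are free of the excluded artifact classes.

## Pipeline choices

* **Filter order** — demultiplex/trim first; the 250 nt minimum length and
  EE ≤ 0.5 thresholds (both inclusive) then describe the biological insert.
* **Identity** — global alignment, match +1 / mismatch −1 / gap −2, identity
  = matches / alignment columns (terminal gaps count).  Implemented with
  Biopython's `PairwiseAligner`, with two provably exact shortcuts: for
  equal-length pairs with Hamming distance d ≤ 2 the ungapped alignment is
  uniquely optimal (identity = (L−d)/L), and any alignment's identity is
  bounded by `1 − k/(2L)` with k the Levenshtein distance (computed by
  edlib), which rejects clearly divergent pairs without alignment.
  Borderline pairs always go through the full aligner.
* **Length handling** — candidate and centroid are truncated to the shorter
  length before identity computation (reads are 5′-anchored prefixes of one
  amplicon); disable with `--no-truncate`.
* **Greedy scan** — uniques sorted by (abundance desc, sequence); a sequence
  joins the *first* centroid at ≥0.99 identity, else founds one; the
  founding sequence remains the comparison centroid.  Ties everywhere break
  lexicographically, making the whole pipeline deterministic.  No
  abundance-skew rule and no chimera filter.
* **Pooling** — clustering runs on all libraries pooled, which is what makes
  "the same phylotype in two libraries" well-defined for the mistag
  analysis.
* **Major phylotype** — argmax of the library's row; ties break by larger
  run total, then id.  An optional fraction check warns (never errors) when
  the major falls below 50%.
* **Mistag fraction** — the default rule counts any-library sharing; the
  stricter variant counts only phylotypes whose home libraries all lie in
  the other termite species.  Both are always reported.  Both rules are
  structurally blind to switches between libraries sharing a major
  phylotype; `switch_visibility` measures that blind spot against the truth
  table (~4.3% of switches in the packaged scenario, explaining the ~0.7
  point downward bias of the 15% recovery).
* **UPGMA** — hand-implemented so the tie rule is specified (clusters keyed
  by smallest leaf label; all-equal distances give a caterpillar in label
  order); scipy's average linkage serves as an independent cross-check in
  the tests.  UPGMA deliberately replaces likelihood tree building: the
  claim under test is separability of host-specific clusters, not
  phylogenetic accuracy, and the monophyly check is strict — it may
  legitimately fail on noisy real data.

## The packaged scenario

45 libraries across 5 hosts: *T. agilis* (9 libraries, 2 phylotypes, in
*R. santonensis*) and *T. sphaerica* / *T. collaris* / *T. postcylindrica* /
*T. campanula* (9 libraries each; 3/3/5/4 phylotypes, in *Z. nevadensis*);
17 phylotypes in total.  The per-host phylotype counts beyond *T. agilis*'s
two are a documented fixture choice reflecting the greater diversity of the
latter two hosts.  With depths of 300–3,000 the scenario yields ~50k–100k
reads per run.

Problem sizes used by the test suite and the acceptance script: ten
end-to-end paper-mimic runs (~75k reads each) for mistag-rate and
phylotype-count recovery; truth-table-level runs (no sequence synthesis)
for the 20-seed majority-robustness and multi-rate estimator-recovery
properties, where only the (origin, observed, phylotype) bookkeeping
matters and clustering fidelity is covered by its own recovery tests.

## Estimator properties worth knowing

* The Fig.-6-style linearity (Pearson r ≥ 0.9 of `f_s` on `o_s`) holds when
  each library carries its own major phylotype.  When libraries share
  majors, `f_s` aggregates over the sharing group, and with i.i.d. depths
  r is bounded by ~`1/sqrt(mean group size)` regardless of depth skew — in
  the packaged scenario (mean group size ≈ 3) r ≈ 0.2 is expected and not a
  defect.  The linearity property is therefore demonstrated on a
  distinct-majors design.
* No relative-abundance cutoff can remove mistagged reads while keeping
  genuine ones once library sizes are skewed enough that a shallow library
  receives more foreign reads of a dominant phylotype than it has genuine
  reads; the demonstration uses an imposed 200 / 20,000 / 8×1,000 depth
  design.
* `M = 0` exactly when switching and errors are both zero, and `M = 0` by
  construction when all libraries share one major — the estimator measures
  cross-library phylotype sharing, nothing else.

## Known limitations

Substitution-only error model (no indels, so the identity fast paths are
exercised on realistic inputs but gapped alignments arise only at the
boundaries); uniform switching destination (no tag-similarity structure);
no modelling of the whole-gut community samples; monophyly check is binary
and unforgiving; greedy clustering is order-dependent by design (documented
and tested, including the A–B–C chain case).
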
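# Methods

This note documents the models, conventions, parameter defaults, and
design decisions behind `genearch`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Survey construction

**Coordinates.** GTF input is 1-based inclusive; everything internal is
0-based half-open on the reference plus strand. Record sequences are in
transcript orientation (reverse-complemented for minus-strand genes), so
all downstream analyses are strand-agnostic by construction; a dedicated
test checks that a transcript and its reverse-complement mirror layout
produce byte-identical records.

**Isoform selection.** One isoform per gene, uniform over that gene's
protein-coding transcripts, ordered by transcript id so the draw depends
only on the seeded generator state, never on annotation file order.
Selecting a single isoform (rather than the longest) avoids biasing the
survey toward genes with long terminal exons.

**Filters.** An intron enters the survey iff (a) length ≥ 32 nt, (b)
canonical GT at positions +1/+2 and AG at −2/−1, and (c) no nested gene.
Genes left with fewer than two retained introns are dropped entirely.
The 32-nt floor guarantees the donor window's 6 intronic nt and the
acceptor window's 20 intronic nt never overlap, so no site is double
counted during model training or motif counting.

**Nested genes.** "Nested" is not a standardized notion; the default
flags an intron when another gene's span (either strand, any biotype) is
entirely contained within the intron. An `overlap` mode (any ≥ 1 nt
overlap) is available via `nested_mode`. Containment is the default
because a gene merely straddling an intron boundary is not inside it.

**Positional classes.** Introns: first / internal / last (a 2-intron
gene has one first and one last intron, no internal). Exons: first /
second / internal / last. IpE units (intron *i* plus exon *i+1*): the
first unit is *cap-proximal* when the first exon is ≤ 250 nt (inclusive
boundary; the first-exon length proxies the distance from the cap-binding
complex), *cap-distal* otherwise.

**Windows with N or overhanging a transcript end** are kept structurally
(the record exists) but excluded from model training, scoring, and motif
counts.

## Maximum-entropy splice-site models

A site's strength is the log2-odds in bits of its window under a signal
vs a background distribution. Both are maximum-entropy fits: among all
distributions over 4^k windows whose marginals over a chosen family of
position subsets match the (pseudocounted) empirical marginals, the
maximum-entropy one is found by iterative proportional fitting (IPF),
starting from uniform and cycling over constraints until the largest
marginal deviation is below `tol` (default 1e-4, `max_iter` 10,000; fits
are flagged when unconverged). The training log-likelihood is
non-decreasing across sweeps, which a test asserts.

**Constraints.** Default for the 9-nt donor: all singletons plus all
adjacent pairs (first- and second-order structure). Two identities pin
the implementation down and are tested exhaustively at k = 3: full
constraints reproduce the pseudocounted empirical joint; singleton
constraints reproduce the product of position-wise marginals.

**Pseudocount.** `pseudocount` (default 1.0) is a *total*
pseudo-observation mass spread uniformly over the 4^k outcomes. Making it
per-cell would let the prior scale as 4^k and swamp any realistic
training set at k = 9 (262,144 cells vs a few thousand windows),
flattening the model; spreading a fixed total mass keeps the prior's
weight independent of window width while still giving every window
positive probability. All empirical targets derive from this one
pseudocounted joint, so the constraint system is always self-consistent
and IPF converges.

**Factorized acceptor.** The 23-nt acceptor window is too large for a
dense table. With the obligate AG held fixed, the remaining 21 positions
are covered by consecutive fragments of 7 positions overlapping by 2
(four fragments: 7 + 5 + 5 + 4 new positions). Each fragment is fitted
densely; the joint is the chain of fragment conditionals
P(x) = P_1(f_1) · Π_i P_i(new_i | overlap_i), with each conditional taken
from the fragment's own distribution. This normalizes to exactly 1 for
any layout (verified exhaustively at k = 6), degenerates to the dense fit
for a single full-cover fragment, and reduces to a product over an empty
overlap. The layout is configuration-exposed; any cover of the modeled
positions is accepted.

**Background (decoy) windows.** Windows from surveyed pre-mRNAs carrying
the obligate dinucleotide at the annotated-site offset (GT at what would
be intron +1/+2; AG at −2/−1) but not annotated as sites, subsampled to
at most 50,000. A zero-order (mononucleotide) background is available as
a fallback. The decoy construction is a design choice of this package;
different choices shift the score scale, which is why strength *medians*
are comparable only within one trained model.

**Quartiles.** Strength classes (weak / moderately weak / moderately
strong / strong) cut at the empirical 25/50/75 percentiles (linear
interpolation); a score equal to a cut belongs to the lower class.

**Serialization** is versioned flat text with full-precision floats;
re-serializing a loaded model is byte-identical.

## Strand asymmetry

Counts are overlap-inclusive (AATAAATAAA contains AATAAA twice): the
hexamers studied self-overlap, and inclusive counting is deterministic
and oracle-checkable. Windows containing N never match. Trims: exons
(3, 3); introns (6, 40) — donor consensus, branch-point/polypyrimidine
region. S is computed from pooled counts per group (Σ Ns, Σ Na, then the
ratio), matching the count-level definition; a per-region mean S is
emitted as a secondary column since the pooled-vs-averaged convention is
genuinely open. Antisymmetry S(m) = −S(revcomp(m)) holds exactly and is
property-tested.

**Co-occurrence analyses** (GGTAAG × AATAAA): (1) per-intron presence of
both motifs vs a 500-nt size cut, Pearson chi-square without continuity
correction (expected counts are large in this design; a degenerate
margin flags the statistic undefined rather than raising); (2) within
~1000-nt introns (band 900–1100), the position of each AATAAA in
co-occurring introns, within vs downstream of the first 500 nt, tested
against the expectation proportional to searchable window positions;
(3) the orientation of the closest GGTAAG–AATAAA pair per intron against
50:50. Co-occurrence uses trimmed interiors, consistent with the DSA
protocol (config-switchable).

## Statistics

* **Kendall tau-b** via the tie-corrected estimator; correlations are
  always computed on raw data, never on windowed medians. Equality with
  an O(n²) all-pairs oracle is tested on random tied vectors up to
  n = 200.
* **Partial tau**: τ_xy·z = (τ_xy − τ_xz τ_yz) / √((1−τ_xz²)(1−τ_yz²)),
  undefined when a controlling correlation is ±1. Its p-value applies
  the normal null approximation for tau to the partial statistic and is
  approximate.
* **Sliding windows**: stable sort by the ranking variable (ties keep
  input order), rolling medians over windows of exactly `window`
  observations (default 2000), step 1.
* **Kruskal–Wallis** with tie correction; all-identical data returns
  H = 0, p = 1 by convention. **KS** two-sample uses the asymptotic
  p-value (the test operates at thousands of observations).
* **IpE randomization test**: per positional group, each of `n_sim`
  simulations draws |actual| introns and |actual| exons uniformly with
  replacement from the group's pools, sums sizes, and KS-tests the
  simulated against the observed size distribution. The overall P is
  the fraction of simulations with KS p ≥ α (default 0.05) — the
  probability that a null re-pairing is indistinguishable from the
  data, so small values mean the observed intron–exon association is
  nonrandom. (The count could equally have been defined over
  *significant* simulations; this implementation fixes it to
  nonsignificant ones, which makes the reported P behave like a
  p-value.) Null calibration holds *marginally*: averaged over
  independently drawn null actual samples, overall P estimates 1 − α.
  Conditional on a single fixed actual sample it spreads widely
  (sd ≈ 0.06 measured) because the actual's own ECDF deviation from the
  null is the same order as the KS statistic's resolution — a property
  of the test's design, at any sample size. The calibration test and
  the acceptance script therefore average over 400 null actuals × 5
  simulations (2,000 total).

## Synthetic genome generator

The generator emulates the statistical signatures the pipeline measures,
not transcription mechanistically.

* **Lengths.** Log-normal per positional class, truncated at a minimum
  (introns 32 nt, exons 10 nt), with the log-mean calibrated by root
  finding so the *truncated* median equals the target. Defaults mirror
  the surveyed fly medians: introns 145/69/65 nt (first/internal/last,
  σ = 1.3/0.9/0.9), exons 233/212/212/596 nt. The sigmas are milder
  than the real heavy-tailed distributions (real first introns have a
  mean an order of magnitude above the median); the generator's purpose
  is controlled recovery, not tail realism. Per-class length quantiles
  are assigned by scrambled stratification (one stratum per class slot,
  shuffled), leaving marginals and couplings untouched while pinning
  realized per-class medians to their targets with O(1/n) error — with
  iid draws the first-intron median's sampling noise at a 5,000-intron
  scale (≈ 4.6%) would be commensurate with the 5% recovery band the
  tests use.
* **Splice sites.** Donor windows sampled from a consensus-based
  position probability model (consensus CAG|GTAAGT, GT fixed) whose
  per-position consensus probability ("sharpness") is drawn per intron:
  w = 0.55 + 0.35 Φ(z₂). Acceptors use a fixed sharpness of 0.75 over a
  polypyrimidine-tract consensus with AG fixed.
* **Size–strength coupling.** A shared Gaussian latent per intron:
  z₁ drives the length quantile, z₂ = ρ z₁ + √(1−ρ²) ε drives donor
  sharpness. The latent Kendall tau is (2/π) arcsin(ρ); the tau
  recovered between extracted length and *fitted score* is attenuated
  (measured ratio ≈ 0.42–0.48 at the default dial, tabulated as the
  generator's documented band 0.2–0.7) because a single 9-nt draw
  observes sharpness noisily. Default ρ = 0.3, emulating the weak
  positive size–strength coupling seen in real surveys.
* **Motif planting.** Each plan inserts a hexamer at sense/antisense
  per-kb rates into a region class, at uniform positions avoiding
  splice-site overlays and each other (rejection sampling, 50 tries per
  insertion). Background occurrences of the motif and its reverse
  complement are first scrubbed from plantable zones (single-base
  changes, bounded passes): the AT-rich background otherwise produces
  strand-symmetric chance hits that dilute every planted asymmetry
  toward 0, making target DSA values unreachable. With scrubbing, the
  realized pooled S converges to (r_s − r_a)/(r_s + r_a). Default plans
  mirror the surveyed fly pattern (AATAAA: −0.03/−0.07/−0.11 in
  first/internal/last introns, +0.24/+0.30/+0.10/+0.21 in
  first/second/internal/last exons; GGTAAG: −0.19 introns, −0.27
  exons, both at modest total rates).
* **Background composition** defaults to 60% A+T (fly introns are
  AT-rich), strand-symmetric by construction (p(A) = p(T),
  p(C) = p(G)). Genes are placed without overlap on one chromosome with
  uniform 200–1000 nt spacers; strands are assigned with probability
  0.5; an optional nested-gene rate plants single-exon gene annotations
  inside large introns to exercise that filter.
* **What the generator does not emulate**, hence what passing tests do
  not show about real data: heavy length tails, compositional
  heterogeneity along genes, correlated intron–exon sizes within IpE
  units (pairs are independent, so the randomization test correctly
  fails to reject on synthetic genomes), alternative splicing beyond a
  single isoform, UTR/CDS structure, and any mechanistic
  transcription/telescripting process.

## Problem sizes and reproducibility

The pipeline's acceptance run uses a 1,250-gene genome (~5,000 surveyed
introns, roughly one-seventh of a full fly survey) and 2,000
randomization replicates per positional group; these sizes give median
recovery to a few percent and Monte-Carlo error below 0.01 on
calibration quantities. One global seed fans out to named substreams
(isoform choice, background sampling, randomization; synthetic
generation takes its own seed), so stages are independently
reproducible; every parameter is recorded in the emitted
`manifest.json`, and re-running from the manifest reproduces the bundle
bit-for-bit.

## Known limitations

* Splice-site scores are calibrated only within one trained model; the
  decoy construction is a package choice, so absolute score medians are
  not comparable across tools retrained on different corpora.
* Partial-tau p-values are approximate (normal theory on a transformed
  statistic).
* The factorized acceptor conditional chain depends on fragment order
  (left-to-right by position here); different consistent layouts give
  slightly different joints.
* `gffutils` builds an in-memory database; very large annotations parse
  slowly, though a full fly-genome survey remains tractable.
* Co-occurrence statistics on small synthetic genomes can be flagged
  degenerate when few long introns carry both motifs; this is reported,
  not raised.
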
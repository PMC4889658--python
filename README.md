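# genearch

Exon–intron architecture analysis of protein-coding genes: splice-site
strength, strand asymmetry of polyadenylation motifs, and the statistics
of intron-plus-next-exon units.

## The scientific problem

Several mRNA-associated processes leave statistical footprints on gene
structure. The nuclear cap-binding complex enhances U1 snRNP recruitment
at the cap-proximal donor splice site (5′ss); 5′ss-bound U1 suppresses
premature cleavage/polyadenylation at nearby polyadenylation signals
(PAS) over a limited downstream range ("telescripting", roughly 500 nt in
*Drosophila*); and 3′-end formation must coexist with splicing of the
last intron. `genearch` provides the measurement machinery for testing
such hypotheses on any annotated genome:

* **Survey construction** — one randomly chosen protein-coding isoform
  per gene; introns retained only if ≥ 32 nt, with canonical GT–AG
  termini, and hosting no nested gene; genes with < 2 retained introns
  dropped. Introns and exons are classified by intragenic position
  (first/internal/last and first/second/internal/last respectively), and
  each intron is paired with its next exon into an **IpE unit** — the
  interval between two consecutive donor sites. First units are split at
  a first-exon length of 250 nt into cap-proximal vs cap-distal.

* **Splice-site strength** — a retrainable MaxEntScan-style scorer. A
  site's strength is `log2 P_signal(w) / P_background(w)` (bits) of its
  window *w* (donor: 3 exonic + 6 intronic nt; acceptor: 20 intronic +
  3 exonic nt). Signal and background are maximum-entropy distributions
  matching empirical marginals over position subsets (singletons and
  adjacent pairs by default), fitted by iterative proportional fitting;
  the 23-nt acceptor window is factorized into overlapping fragments
  whose conditional chain is exactly normalized. Background windows
  carry the obligate GT/AG at the annotated offset but are not annotated
  sites.

* **DNA strand asymmetry (DSA)** — for a motif with sense/antisense
  counts `Ns`, `Na` in a region set,

  ```
  S = (Ns − Na) / (Ns + Na)
  ```

  computed on pooled counts after trimming biased flanks (3 nt at both
  exon ends; 6 nt at intron 5′ ends, 40 nt at intron 3′ ends). Negative
  S reads as counter-selection on the sense strand. Default motif set:
  AATAAA, the weaker PAS variants ATTAAA/AATATA/TATAAA, the 5′ss-like
  GGTAAG, and the anagram controls TAAAAA/AAAAAT.

* **Statistics** — Kendall tau-b and partial tau, Kruskal–Wallis,
  two-sample Kolmogorov–Smirnov, chi-square tests, sliding-window
  medians (rank by one variable, roll medians of the others over
  windows of 2000 observations, step 1), and a randomization test that
  compares observed IpE-unit sizes per positional group against null
  re-pairings of introns and exons (overall P = fraction of re-pairings
  indistinguishable from the data at KS p ≥ 0.05).

* **Synthetic genomes** — a generator that emits FASTA + GTF + ground
  truth with planted class-specific length medians, splice-site strength
  (with an optional latent coupling between intron length and donor
  strength), and motif planting at controlled sense/antisense rates to
  realize target DSA values, so every stage is testable without
  downloads.

## Worked example

```python
from genearch import SyntheticGenomeSpec, generate, RunConfig, run_pipeline

paths = generate(SyntheticGenomeSpec(n_genes=300), seed=7).write("demo_genome")
cfg = RunConfig(fasta=str(paths["fasta"]), gtf=str(paths["gtf"]),
                outdir="demo_out", seed=7, n_sim=500)
results = run_pipeline(cfg)
print(results["table1"].round(2).to_string(index=False))
```

prints the per-class survey summary:

```
pos_class   n  intron_size_mean  intron_size_median  exon_size_mean  exon_size_median  donor_mean  donor_median  acceptor_mean  acceptor_median
    first 300            308.02               145.0          316.77             211.5        5.16          5.13          14.34            15.04
 internal 636             95.44                69.0          317.43             212.0        5.07          5.00          14.10            13.95
     last 300             88.83                65.0          974.61             596.0        5.38          5.50          13.73            14.14
```

The class intron-size medians (145/69/65 nt) and next-exon medians are
the generator's planted values, recovered through annotation parsing,
isoform selection, filtering, and classification. The DSA table from the
same run recovers the planted asymmetry pattern of the canonical PAS —
favored in exons, counter-selected in introns:

```
 motif   kind region_class  n_regions  Ns  Na      S
AATAAA   exon        first        300 121  74  0.241
AATAAA intron        first        300  77 104 -0.149
AATAAA intron         last        300  15  15  0.000
```

and the randomization test reports `overall_P ≈ 0.99` per positional
group — correctly *failing to reject* the null here, because the
generator pairs intron and exon sizes independently.

The same pipeline runs on real data, e.g. an Ensembl genome/annotation
pair (`*.dna.toplevel.fa.gz` + `*.gtf.gz`), via the CLI:

```
genearch all --fasta genome.fa.gz --gtf annotation.gtf --outdir survey --seed 1
```

Subcommands `simulate`, `extract`, `train`, `score`, `dsa`, and `stats`
expose the individual stages; see `genearch --help`.

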
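# pirnaclust

Probabilistic detection, scoring and visualization of genomic piRNA
clusters from small-RNA mapping data.

Piwi-interacting RNAs (piRNAs, ~26–32 nt) guard animal germline genomes
against transposable elements. Most piRNAs derive from genomic *piRNA
clusters* — loci transcribed mono- or bi-directionally into long precursors
that are processed into thousands of mature piRNAs. Given a file of
genome-mapped small-RNA reads, `pirnaclust` detects cluster candidates as
regions of significant read density and then verifies each candidate
against the decisive piRNA-cluster characteristics: strand asymmetry,
typical read length, 1T/10A base composition and enrichment of infrequently
mapped reads. It is written for small-RNA/genomics researchers who need
reproducible, threshold-explicit cluster calls rather than heuristic
density cutoffs.

## Model

**Density null.** Under a uniform mapping null, hits per 1 kb window on a
chromosome with *H* hits and length *L* are Poisson with mean
λ = 1000·*H*/*L*. The mass function is extended to rational hit numbers
with the gamma function, *f*(*x*) = e^−λ λ^*x* / Γ(*x*+1), and the minimum
hit density is the smallest *k* ∈ {0.1, 0.2, …} hits/kb with
*P*(*x* ≥ *k*) ≤ α. Candidates are collected with a sliding window of *n*
hits (the dataset's minimum loci per cluster) tagging every window whose
span reaches *k*, and refined by stepwise clipping of peripheral hits.

**Characteristic scores.** For a cluster of *n* loci of which *m* show a
property with dataset probability *r*,

```
score = −log10( Σ_{k=m..n} C(n,k) · r^k · (1−r)^(n−k) )
```

so a score of 2.0 corresponds to a tail probability of 0.01. The score is
applied with r = 0.5 to the main-strand hit count (strand bias), with the
dataset's typical-length ratio, and with the dataset's (or a uniform 25%)
1T/10A ratio — scoring whichever of 1T and 10A is stronger, never the sum.
Enrichment of infrequently mapped reads is measured by the
normalized-hits/total-hits ratio (NTR, Σ 1/genomic-hits over loci divided
by *n*) and scored through an 8-group approximation of the read-multiplicity
distribution. Scores are capped at 100 (tail < 10⁻¹⁰⁰); clusters above 1000
loci are scaled down proportionally.

The default preset (α = 0.01, all minimum scores 2.0) is the Bonferroni
per-test level for a family-wise α = 0.05 over the five tests. Each
reported cluster carries the combined probability that its deviations arose
by chance, and the run reports the probabilities of 0, ≥1 and ≥2 mistakenly
annotated clusters in the final set.

## Worked example

Generate the built-in worked example (one mono-directional cluster, one
bi-directional cluster, and a decoy accumulation of multi-copy loci on a
1 Mb chromosome) and detect at defaults:

```
pirnaclust simulate --preset toy --seed 20120110 --out demo/sim
pirnaclust detect --input demo/sim/mapped.eland3 \
    --chrom-sizes demo/sim/chrom.sizes --out demo/results
```

The log reports the derived thresholds and the outcome:

```
INFO pirnaclust.pipeline: min hit density 1.8-1.8 hits/kb, min loci per cluster 13
INFO pirnaclust.pipeline: 3 cluster candidates
INFO pirnaclust.pipeline: accepted 2 clusters; P(0/>=1/>=2 mistaken) = 1/0/0
```

With 100 hits on 1 Mb (λ = 0.1 hits/kb) the density significant at
α = 0.01 is 1.8 hits/kb, and 13 loci are needed for an ideal cluster to
reach every minimum score with this dataset. `demo/results/
clusters.summary.tsv` then lists the two accepted clusters:

```
chromosome  start   end     size_nt  hits  score_strand_bias  score_typical_length  score_t1_or_a10  score_ntr  score_sum  directionality
chr1        98759   105158  6400     27    6.6807             2.2956                2.8261           15.5623    27.3647    mono
chr1        500072  503590  3519     25    4.1065             3.8725                3.7800           14.3846    26.1437    bi
```

Every characteristic clears the 2.0 minimum — e.g. the mono cluster's
strand-bias score 6.68 means its strand asymmetry had probability
10⁻⁶·⁷ under the fair-strand null — and the bi-directional cluster is
recognized from its divergent halves. The decoy is rejected
(`rejected.tsv`) with strand-bias score 0.88 and 1T/10A score 0.02: a dense
accumulation of frequently mapped reads without the asymmetry or
composition of a transcribed cluster. Each accepted cluster also gets a
FASTA file of its loci and an SVG picture (plus-strand loci drawn upward,
minus-strand downward, multi-copy loci in red), plus a BED6 track.

## Layout

- `src/pirnaclust/io_eland3.py` — ELAND3 (SeqMap) parsing, chrom sizes
- `src/pirnaclust/dataset.py` — dataset profile, 8-group read partition
- `src/pirnaclust/density.py` — gamma-extended Poisson density thresholds
- `src/pirnaclust/detection.py` — sliding window, peripheral clipping
- `src/pirnaclust/scoring.py` — binomial-tail scores, NTR machinery
- `src/pirnaclust/classify.py` — verification, directionality, rescue
- `src/pirnaclust/reporting.py` — summary / FASTA / SVG / BED writers
- `src/pirnaclust/simulate.py` — synthetic landscapes with planted clusters
- `src/pirnaclust/cli.py` — `pirnaclust detect | simulate | render`

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
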
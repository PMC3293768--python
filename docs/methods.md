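# Methods

## Input model

The detector consumes per-occurrence mapping files in the ELAND3 dialect of
the SeqMap aligner: one tab-separated line per mapping occurrence
(target, coordinate, target sequence, read identifier, read sequence,
mismatch count, strand), coordinate-sorted within each chromosome.
Coordinates are 1-based inclusive; BED exports convert to 0-based
half-open. Reads are deduplicated by normalized sequence (uppercased,
U→T); a read's *genomic hits* is its occurrence count across the whole
file, and its *copy number* (sequencing frequency) is parsed from the
identifier with a configurable pattern (default: the trailing integer,
e.g. `piR-7_x15` → 15), defaulting to 1 — transcription information is
optional. Column order is remappable for non-standard dialects. Hits with
mismatches are accepted; an optional maximum-mismatch filter drops
occurrences without changing per-read hit counts. Chromosome lengths come
from a two-column sizes file; absent entries fall back to the maximum hit
end coordinate (logged as approximate, and only safe when hits reach near
the chromosome end).

## Density null and detection

Under the uniform null, the hit count in a 1 kb window of a chromosome
with H hits and length L is Poisson with mean λ = 1000·H/L. The Poisson
mass is extended to rational x via f(x) = e^−λ λ^x / Γ(x+1), and
P(x ≥ k) is evaluated as the unit-step sum Σ_j f(k+j), truncated once a
term beyond the mode falls under 10⁻¹⁵ of the running total; at integer k
this is the exact Poisson survival function. The minimum hit density is
the smallest k on a 0.1 hits/kb grid with P(x ≥ k) ≤ α, computed per
chromosome (zero-hit or sub-kb chromosomes are skipped with a log entry).
λ deliberately includes cluster hits — no attempt is made to remove the
mild circularity of clusters raising their own chromosome's background
rate; for realistic datasets the effect on k is below the 0.1 grid step.

The minimum number of loci per cluster is the smallest n for which an
ideal n-locus cluster (all hits on one strand, all typical length, all of
the stronger 1T/10A branch, all reads from the lowest-multiplicity group)
reaches every enabled minimum score with the given dataset; characteristics
whose dataset ratio makes the threshold unattainable (e.g. typical-length
ratio 1) are excluded from the search with a warning.

Detection slides a window of n consecutive hits; a window whose
hit-boundary span s satisfies n·1000/s ≥ k tags its hits, and chains of
overlapping qualifying windows become cluster candidates. A candidate
whose overall density falls below k (possible when dense sections chain
across a sparse middle) undergoes peripheral clipping: for total clip
count c = 1, 2, … every split into u upstream and d = c−u downstream
removals is tried, the first c admitting a remainder with density ≥ k and
≥ n hits wins, keeping the maximal-hit cluster (ties: higher density, then
fewer upstream removals). Clipped-off fragments re-enter the candidate
queue once, so each hit is processed at most twice. Density of a hit set
is always count·1000/(last end − first start + 1); the hit-boundary span
was chosen for determinism since window span endpoints are otherwise
underdetermined.

Window reach: a qualifying window may span up to n·1000/k nt, so a
candidate boundary can extend up to roughly that distance beyond the last
truly clustered locus when stray background hits fall nearby. At α = 0.01
on a 1 hit/kb background this is ≈1.5 kb; reported cluster borders carry
that much uncertainty (see Limitations).

## Characteristic scores

All four scores are binomial upper tails reported as log10 reciprocal
probabilities: score = −log10 Σ_{k=m..n} C(n,k) r^k (1−r)^{n−k}, evaluated
in log space (log-gamma terms combined with log-sum-exp) because r^k
underflows at realistic n. A score of 2.0 corresponds to a tail of 0.01.
Tails below 10⁻¹⁰⁰ score exactly 100, the global cap. Clusters above 1000
loci have n set to 1000 and every m scaled proportionally (half-up
rounding) before scoring; this may underestimate scores but such clusters
saturate the cap regardless.

- **Strand bias** — r = 0.5, m = hits on the main strand. Verification
  scores the better of the two cluster topologies: the whole-cluster
  main-strand count, or the summed fragment-wise main-strand count at the
  best admissible bi-directional split. Without the latter, genuinely
  bi-directional clusters (m ≈ n/2 cluster-wide) could never pass a
  strand minimum — the fragment reading expresses that their halves are
  individually strand-asymmetric.
- **Typical length** — r = dataset fraction of loci whose read length lies
  in the configured typical range (default 26–32 nt). A degenerate
  dataset ratio (0 or 1) disables the score with a warning.
- **1T/10A** — the better of the 1T branch (T at read position 1) and the
  10A branch (A at position 10; reads shorter than 10 nt never count),
  never the sum, so datasets of primary piRNAs, ping-pong piRNAs or both
  are all handled. Branch ratios come from the dataset or, in
  `uniform` composition mode, are fixed at 0.25.
- **NTR** — the normalized-hits/total-hits ratio, Σ 1/genomic-hits over
  cluster loci divided by n; 1 exactly iff every read maps once. To avoid
  enumerating multiplicity combinations, reads are partitioned into 8
  groups by ascending genomic hit count (quantile split, remainders to the
  earliest groups; with fewer than 8 reads, empty groups inherit the
  previous mean). For each pair (i, i+4) the minimum count
  m_i = ⌈ n·(NTR − 1/a_{i+4}) / (1/a_i − 1/a_{i+4}) ⌉ of group-i reads
  reaches the observed NTR assuming all others come from group i+4, and
  the score is −log10 of Σ_i Σ_{k=m_i..n} C(n,k) (r_i/R)^k (r_{i+4}/R)^{n−k}.
  Pairs that cannot reach the observed NTR (including m_i > n, and
  degenerate pairs a_i = a_{i+4} with 1/a_i below the observed NTR)
  contribute an empty sum; degenerate pairs that can reach it contribute
  their full pair mass ((r_i+r_{i+4})/R)^n. The pair probabilities are
  evaluated exactly as stated, without renormalization. With a quantile
  partition the four pair masses total at most ≈4·(1/4)^n, so this score
  is permissive for any cluster of nontrivial size and acts mainly as a
  sanity floor; cluster rejection in practice is driven by the strand and
  composition scores (see Limitations).

All ratios entering the scores are locus-weighted (each mapping occurrence
counts once) and unweighted by copy number: the scores compare cluster
loci against dataset loci, and copy numbers enter only the visualization.

## Verification, directionality and error accounting

A candidate is accepted iff every enabled score reaches its minimum
(defaults: 2.0 each, with α = 0.01 — the Bonferroni per-test level for a
family-wise 0.05 over the five tests). The degree of mono-directionality
is the main-strand hit fraction; the degree of bi-directionality is the
best pro-rata combination of fragment-wise main-strand fractions over
splits whose fragments each hold ≥25% of hits or ≥10 hits. A cluster is
mono if its mono degree passes the threshold (default 0.75) and is at
least the bi degree (ties favour the simpler topology), bi if the bi
degree passes and strictly exceeds mono, else non-directional. Degrees
count hits, not copy numbers.

The optional rescue pass re-evaluates candidates rejected for missing
strand asymmetry after removing loci of reads with more than a stated
maximum of genomic hits (the flag's spirit is the classical "reads mapping
1–5 times" filter); the reduced candidate must still satisfy the density
and minimum-locus requirements and the full verification. Rescued clusters
are flagged in the output.

Each accepted cluster's combined chance probability is the product of its
enabled criteria's tail probabilities (floored at 10⁻³⁰⁰) — an
independence assumption across criteria. Under an independent-Bernoulli
model over the reported set, the run reports P(0), P(≥1) and P(≥2)
mistakenly annotated clusters; P(0) + P(exactly 1) + P(≥2) = 1.

## Synthetic landscapes

The generator emulates the null and the signal: background hits uniform
per chromosome (1 kb window counts verified Poisson by goodness-of-fit in
the tests), with planted clusters controlling span, locus count, strand
model (mono with main-strand probability, bi with central divergence, or
uniform for decoys), 1T/10A probabilities, length distribution, per-read
multiplicity and copy numbers. Multi-mapping is realized by emitting one
read sequence at several positions — uniformly genome-wide, except for
uniform-strand decoy regions whose extra placements stay in-region to
reproduce untranscribed accumulations of multi-copy loci. Defaults for the
benchmark landscape: 10 Mb chromosome, 10 000 background hits (1 hit/kb,
lengths 18–35 nt, 25% 1T, 10% multi-mapping reads with 2–20 hits) and
mono clusters of 50 loci in 5 kb spans (10 hits/kb, p_main 0.9, 75% 1T,
26–32 nt) — sizes and densities of well-supported mammalian clusters while
keeping a full 20-landscape benchmark under ten seconds. The toy fixture
(100 lines) plants one mono cluster, one bi cluster and one multi-copy
decoy on 1 Mb.

What the simulations do *not* emulate: genomic sequence (reads are random,
so mappability structure, repeat families and true multi-mapping geometry
are absent), ping-pong 10 nt overlap signatures beyond marginal 1T/10A
frequencies, expression-level dispersion, and chromosome-scale rate
heterogeneity. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under its own null, not performance on any
real library.

## Numerical choices

- Tail sums in log space via log-gamma and log-sum-exp; verified against
  50–60-digit arbitrary-precision summation to 10⁻⁹ on the score scale.
- The extended-Poisson tail truncates at relative term size 10⁻¹⁵ past the
  mode; density thresholds sit on an exact 0.1 grid (integer steps / 10).
- m_i ceilings use a 10⁻⁹ slack to absorb float error in 1/a terms.
- Ties: main strand → plus; equal-c clip splits → higher density then
  fewer upstream removals; equal directionality degrees → mono; equal
  bi-split values → leftmost split.
- Empty inputs: profiling and scoring raise on empty collections; the CLI
  treats an empty mapping file as a clean run with an empty summary.

## Limitations

- Cluster borders inherit the sliding window's reach (≈ n·1000/k nt), so
  at low background densities boundaries can overshoot the transcribed
  region by 1–2 kb; downstream analyses needing precise borders should
  trim against annotation or expression evidence.
- With the quantile group partition, the grouped NTR tail is small for any
  sizable cluster, so multi-copy accumulations are in practice rejected by
  the strand and composition criteria rather than by NTR. A partition by
  absolute hit-count ranges would sharpen NTR discrimination but makes the
  score reject legitimate mostly-unique clusters of moderate size; the
  quantile reading was kept.
- The background rate is chromosome-wide; locally elevated mappability or
  assembly artifacts are not modelled.
- The combined chance probability multiplies per-criterion tails as if
  independent; the set-level error probabilities are therefore
  approximations, not calibrated family-wise error rates.
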
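# Methods

This note documents the models, numerical choices and limitations behind
`srnapipe`. The package re-implements, as a tested library, the
computational analysis typical of unreplicated small-RNA sequencing
studies: three deeply sequenced libraries (an untreated Control and two
treatment stages), profiled for conserved miRNAs, novel hairpin-derived
candidates, and per-miRNA expression differences, with no biological
replication.

## The exact count test

The core statistic compares a miRNA's counts between two libraries without
replicates. Conditional on observing `x` reads among `N1` clean reads in
library A, the count `y` among `N2` clean reads in library B is modeled by

    p(y | x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1 + N2/N1)^(x+y+1) )

which is a negative-binomial distribution in `y` with `x + 1` successes and
success probability `N1/(N1+N2)` — the classical exact test for comparing
two sequencing libraries of known depth. Both tails are always reported:

- lower tail `C(y' ≤ y | x)`, evidence for *down*-regulation in B,
- upper tail `D(y' ≥ y | x)`, evidence for *up*-regulation in B.

Inclusive tails overlap at the observed point, `C + D = 1 + p(y|x)`.
A useful exchange identity (used as a test) is that swapping the library
roles maps the *strict* upper tail onto the inclusive lower tail:
`D(y' > y | x; N1,N2) = C(x' ≤ x | y; N2,N1)`; the naive inclusive-inclusive
"symmetry" differs by exactly the observed-point pmf.

**Sidedness.** The reported p-value defaults to twice the smaller tail,
capped at 1 (two-sided). This choice reproduces the printed significance
calls of the worked examples the package is validated against, including
three p-values to all printed digits; the one-sided tail is available via
`DEConfig(sided="one")`.

**Numerics.** The pmf is evaluated in log-gamma space. The smaller tail is
summed directly (vectorized log-sum-exp, 4096-term chunks); summation stops
once the running term falls below 1e−18 of the accumulated sum, and the
complementary tail is obtained from the overlap identity. This is stable
for counts up to 10⁶ (verified against a 50-digit arbitrary-precision
summation and against the scipy negative-binomial in the tests).
P-values below double-precision underflow report as exactly 0.

**Normalization and fold change.** Expression is reads-per-million of
clean reads; a zero count is replaced by the pseudo-count 0.01 so ratios
stay finite (this makes the smallest detectable "fold change" against a
zero depend on depth — a known property of the convention, not removed
here). Fold change is `log2(second/first)` with the second library treated
as the treatment. Pairs with `x + y < 20` are skipped by default; note the
published worked table this reproduces itself contains rows below that
threshold, so the worked-example checks set `min_pair_reads=0` explicitly.

## Hairpin discovery

Folding is base-pair maximization (Nussinov recursion) over Watson–Crick
plus GU pairs with a minimum hairpin loop of 3, with a deterministic
traceback (pair the outermost bases when optimal, else split at the 5'-most
optimal point). This replaces thermodynamic minimum-free-energy folding: a
screen that only asks "does a clean stem-loop exist with the read on one
arm?" does not need energies, and pair maximization is exactly checkable
against brute-force enumeration of all non-crossing pairings (done for 200
random short sequences in the tests). The trade-off is that maximization
can favor geometrically different structures with equal pair counts, which
motivates the tag-anchored screen below.

Each unannotated tag is exactly mapped to the genome (both strands; > 5
loci discards the tag as repeat-derived), and two windows per locus are
extracted (tag + 70 nt downstream, and 70 nt upstream + tag), covering the
36–91 nt precursor range of interest. The screen then works outward from
the pairs the tag itself makes:

1. tag pairs must all point in one direction (pairing with itself or both
   ways means the tag crosses a terminal loop → `spans_loop`; no pairs →
   `off_stem`);
2. the tag's helix is extended inward and outward, allowing at most 4
   unpaired/bulged bases per step on each side;
3. the enclosed terminal loop must be 3–20 nt, the helix ≥ 18 pairs, ≥ 14
   tag bases paired into it, and no > 4 nt unpaired run inside the tag.

Thresholds approximate the defaults of the standard hairpin-screening
tools and are all configurable (`HairpinThresholds`). Passing candidates
are trimmed to the helix extent (plus unpaired tag edges), so the reported
`segment:start..end:strand` precursor coordinate describes the hairpin
rather than the extraction window; duplicate loci are merged with support
summed. Candidates need ≥ 10 total supporting reads by default — the
read-count floor such studies state, kept configurable because published
candidate tables routinely contain entries below their own stated floor.

## Annotation model

Categories are assigned by a priority walk (rRNA > tRNA > snRNA > snoRNA >
exon-sense > exon-antisense > known miRNA > unannotated; the order is
configurable and echoed in summaries, since source studies rarely state
theirs). ncRNA/exon hits are exact substring matches in RNA space;
known-miRNA hits allow ≤ 2 substitutions and ≤ 2 nt overhang at each
terminus on both sequences, with ≥ 10 nt overlap — isomiR termini vary,
substitutions should stay rare. Equal-quality hits resolve to the fewest
mismatches, then the lexicographically first name (logged). A mature's
count is the sum of its assigned tags' counts, so isomiRs accumulate onto
their annotated mature.

## Clustering

Expression profiles are log2(normalized + 0.01), median-centered per row,
under the `1 − Pearson r` distance with average linkage (the combination
popularized by the classic gene-cluster/tree-view tools). Rows are sorted
by name before distancing so ties and leaf order are deterministic;
constant rows have undefined correlation and are placed at distance 1 from
everything (with a warning). The scipy implementation is cross-checked
against a hand-written O(n³) agglomeration in the tests. Trees export as
newick with branch lengths.

## Synthetic data: what it emulates, and what it does not

No raw data exist for the study design this package models, so the
generator is first-class, tested code that defines the study conditions:

- **Libraries.** Three independently sampled libraries; default totals are
  configurable (20,000 reads in the default config; the recovery analyses
  use 100,000 per library, scaled down from the ~10⁷ of a real run purely
  for turnaround). Reads are fixed 50 nt instrument-style: insert +
  3'-adapter + random padding, forcing the trimming stage to work.
- **Composition.** ~55% of reads from a panel of mature miRNAs (default 30
  matures in 10 families) embedded in hairpin precursors embedded in genome
  segments; ~23% ncRNA/exon fragments (rRNA 10%, tRNA 6%, sn/snoRNA 1.5%
  each, exon sense 3% / antisense 1%); planted novel-hairpin arm reads;
  the remainder unannotated background. ~6.9% of reads are planted
  cleaning rejects (adapter-only, low-quality, too short, too long),
  matching the raw→clean attrition of real libraries of this type.
- **Length and 5' bias.** Mature lengths concentrate at 22–23 nt so that
  > 50% of inserts fall in 20–24 nt; matures of length 20 and 22 start
  with U and the unannotated background leans 5'-U (0.4), reproducing the
  5'-uridine bias real libraries show, strongest at lengths 20 and 22.
- **Ground truth.** A truth table fixes per-library intended counts; reads
  are drawn multinomially, so realized composition converges to intended
  with binomial fluctuations. Planted fold changes are applied as exact
  per-miRNA rate multipliers (default: the first mature ×4 in the second
  library), with residual mass absorbed by the unannotated slice so the
  ratio is exact. Intended log2 fold changes recorded in the truth equal
  the log-ratio of intended per-million rates by construction.
- **Hairpins.** Planted precursors are near-perfect stems (mature arm + 4–8
  nt extension, 6–12 nt loop) with two non-pairing wobbles facing the
  mature's middle — real precursors are imperfect, and the wobbles also
  keep the arm's exact reverse complement out of the genome so arms map
  uniquely. Each hairpin is verified discoverable by the package's own
  screen in its final genomic context (and redrawn otherwise, ~5% of
  draws): the generator's contract is that planted hairpins are findable,
  which is what makes recall-1 recovery a meaningful regression check.

Not modeled: ligation/sequence bias, PCR duplication structure,
instrument error profiles (an optional uniform substitution rate exists,
default 0), multi-isoform expression from one precursor, and genomic
repeats. Passing recovery tests therefore demonstrates the pipeline's
correctness on idealized data — they say nothing about adapter-heterogeneity,
chimeras, or mapping ambiguity in real libraries.

## Reproducibility

All randomness flows through numpy Generators seeded from explicit
arguments; the pipeline derives per-stage sub-seeds by hashing stage names
so toggling one stage does not shift another's stream. Outputs are plain
text with 6-significant-digit reals, and the run manifest records SHA-256
digests of every artifact; identical configs produce identical digests.

## Known limitations

- Adapter trimming is exact-match; one sequencing error in the adapter
  loses the read (acceptable at error rate 0, conservative otherwise).
- The exact test treats library depth as fixed and known; like all
  unreplicated designs it confounds biological and technical variation,
  and no multiple-testing correction is applied (none is applied in the
  studies this reproduces).
- Base-pair maximization ignores stacking energetics; a thermodynamically
  marginal but pair-rich structure can pass the screen. Thresholds (b)–(e)
  are the guard against this.
- Conserved-miRNA identification reports both raw-hit and distinct-mature
  tallies; published per-library totals conflate the two, so neither is
  labeled as "the" published quantity.
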
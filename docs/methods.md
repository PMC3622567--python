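# Methods

## Promoter definition and extraction

A promoter is the fixed-length region (default 1000 nt) immediately 5' of
the translation start codon, read 5'→3' toward the ATG. Anchoring on the
ATG rather than the transcription start site is deliberate: ATG positions
are available uniformly across annotations, at the cost of including 5'UTR
sequence of variable length. External coordinates are 1-based inclusive
(GFF3 convention); internally all arithmetic is 0-based half-open. For GFF3
input the translation start is min(CDS start) on the + strand and max(CDS
end) on the − strand, with CDS rows grouped through their mRNA parent to
the gene; multi-isoform genes therefore contribute one promoter anchored at
the most upstream coding position.

Genes closer to a contig edge than the requested length are retained with a
shorter sequence and counted in the log, never dropped: the per-1000
normalization divides by the number of promoters scanned, so dropping
truncated genes would silently change densities. Ambiguity codes in input
genomes are masked to N, and N matches no motif character.

## Dyad scanning

A dyad is `MOTIF(N)MOTIF` with spacer length 0 ≤ N ≤ 30. The cap of 30
reflects the observation that cooperatively binding transcription factors
are usually spaced within ~25 bp. Scanning is exact string matching on the
extracted strand only; ACGT is its own reverse complement, so its dyad
counts are strand-symmetric, and the eight controls are scanned under the
identical single-strand convention so the comparison is like for like.

Counting convention: **all ordered occurrence pairs** within range count.
In a run `ACGT-x-ACGT-y-ACGT`, three dyads are reported when all gaps are
in range, and spacers may themselves contain motif copies. This is the only
convention under which "frequency at the same N" is well defined when
motifs nest inside spacers; an `adjacent_only` mode (consecutive
occurrences) is available for sensitivity analysis. Both dyad counts and
distinct dyad-carrying gene counts are emitted, since either could be the
quantity of interest for the per-1000 figure.

## Peaks, dips and windowed conservation

Preferred/avoided spacer lengths are profile values strictly outside the
10th/90th percentile whiskers of the 31-point profile itself. Percentiles
use linear interpolation between order statistics (the inclusive, type-7
method); with 31 points any reasonable method flags the same gross
outliers, and both percentile levels are configurable. "Common peaks" across
species are the plain intersection of per-species peak sets, with no
additional test.

Conservation between two species is the Pearson r over every window of
w ≥ 6 consecutive spacer lengths (Σ_{k=6..31}(31−k+1) = 351 windows for a
31-point profile), with t = r·√((w−2)/(1−r²)) and a two-sided p-value on
w − 2 df. The best window per width summarizes the most conserved runs; the
full-width window is the whole-profile correlation and is also what is
computed on ortholog-restricted profiles. Correlations are computed on raw
counts — per-1000 scaling is affine and leaves r unchanged. No
multiple-testing correction is applied over the 351 windows; window
p-values are descriptive, not family-wise error rates.

Ortholog-group profiles are emitted both as summed counts and per-gene
averages (counts divided by the number of subset genes); correlation is
identical for the two because the scaling is uniform within a species'
subset.

## Spacer consensus

For each N the position-wise percentages of A, C, G, T are computed over
all observed spacers of that length — over dyad occurrences, not over
promoters, so a promoter with several dyads contributes each spacer once.
A base qualifies at a position when it clears an asymmetric threshold:
25% for G or C, 40% for A or T. The asymmetry matches a ~36% GC genome
background, where the null expectation is ≈18% per G/C and ≈32% per A/T:
both thresholds sit roughly 7–8 points above their null. The IUPAC code for
exactly the qualifying set is emitted — single letters, S for {G,C}, the
other degenerate codes for larger or mixed sets (the unique consistent
extension of the single-letter scheme), and N for the empty set. A
consequence worth knowing: an exactly uniform composition (25% per base)
qualifies G and C but not A or T and reads S, while random 36%-GC
background reads N; only genuinely constrained positions escape N.
Ambiguous characters are excluded from numerator and denominator at their
position. Raising either threshold can only shrink qualifying sets, so
consensi degrade monotonically toward N.

## Likelihood of occurrence and the Grubbs screen

For a condition's regulated gene set A within a universe U (all genes with
promoters) and the dyad-carrying set B(N),

    L(N) = [|A∩B(N)| / |B(N)|] / [|A| / |U|],

the fold by which regulation is enriched among dyad carriers; L = 1 is
chance and L(N) is undefined when B(N) is empty. The overall statistic uses
B_any, the union of B(N) over N = 0..30 ("carries at least one dyad").
Conditions with overall L > 1.30 (configurable; 1.20 is sensible for
smaller gene universes) proceed to a one-outlier Grubbs test on the nine
overall likelihoods (ACGT + 8 controls): G = max|xᵢ − x̄|/s with sample sd,
compared to the critical value

    G_crit = ((n−1)/√n) · √(t²/(n−2+t²)),

t the upper α/(2n) (two-sided) critical value of Student's t with n − 2 df.
Two-sided is the default (critical value 2.21 at n = 9 and α = 0.05; the
one-sided value is 2.11), matching standard outlier-screen practice when
either direction would be surprising; sidedness is configurable. A condition is
called significant only when ACGT is itself the extreme point *and*
G > G_crit; without the first clause an outlying control would flag the
condition. This makes the screen conservative: under the null, G > G_crit
occurs at ≈ α, but the extreme point is equally likely to be any of the
nine motifs, so full significance is rarer than α. No correction is applied
across conditions.

## Synthetic data: what it emulates and what it does not

The generator draws i.i.d. bases with P(G) = P(C) = gc/2 (default
gc = 0.36) and plants `motif+spacer+motif` constructs at Poisson rates per
spacer length (a fixed-count mode exists for exact small fixtures), with
uniform non-overlapping offsets and background-distributed spacer bases.
Ground truth is defined **post-rescan**: the scanner is re-run on the final
sequences and that profile is the oracle, because background sequence
creates incidental ACGT copies and planted constructs can pair across
insertions — this choice makes generator-vs-scanner tests exact rather than
probabilistic. Condition gene sets are drawn so dyad carriers are regulated
at fold × p and non-carriers at the probability that preserves the marginal
p, giving a known true overall L = fold. Species families share planting
rates perturbed by lognormal noise, with gene ids aligned 1:1 as a trivial
ortholog table.

What synthetic data does *not* contain: promoter grammar (TATA boxes,
nucleosome positioning), autocorrelated GC structure, isochores, repeats,
gene-density variation, or realistic ortholog divergence. Passing tests on
synthetic data therefore validate the bookkeeping and the statistics — the
scan is exact, the normalizations are consistent, planted signal of
realistic size is recovered, null calibration holds — but say nothing about
which spacer lengths real genomes prefer.

## Numerical choices

- Percentile method: inclusive linear interpolation (type 7), configurable.
- Zero-variance correlation windows are skipped with a warning rather than
  reported as NaN rows.
- |r| = 1 yields an infinite t and p = 0 by convention.
- Grubbs on a zero-variance panel is undefined; the screen reports the
  condition as unscreened rather than erroring the whole run.
- L(N) with empty B(N) is NaN and excluded from summaries.
- Ties in the Grubbs extreme point break to the lowest index.
- Seeding: every generator takes an explicit integer seed; per-promoter
  substreams are derived from (seed, stage, promoter index), so subsets and
  reruns are bit-reproducible.

## Problem sizes used in the test and acceptance runs

Simulation-based checks run at desk scale chosen to keep the full suite
fast while leaving the statistics well-resolved: scanner-oracle agreement
on 1000 random 1 kb sequences × 9 motifs; planted-peak recovery on four
species of 150 × 1 kb promoters (planting rates 0.1/0.8/0.1 at
N = 0/7/14); enrichment recovery on a 10,000-gene universe with 1000 dyad
genes, P(regulated) = 0.2 and 200 replicates per fold. Whole-genome runs
(tens of thousands of promoters) use the identical code paths and complete
in minutes on one CPU.

## Whole-genome reproduction workflow

Per-1000 dyad densities for real genomes require the genome builds on
disk. With a genome FASTA and annotation per species:

```bash
acedyad extract --fasta TAIR10.fa --annotation TAIR10.gff3 --format gff3 \
    --length 1000 --species arabidopsis --out arabidopsis.promoters.fa
acedyad scan --promoters arabidopsis.promoters.fa --controls default \
    --out arabidopsis.profiles.tsv --hits-out arabidopsis.hits.tsv
python - <<'PY'
import pandas as pd
df = pd.read_csv("arabidopsis.profiles.tsv", sep="\t")
acgt = df[df.motif == "ACGT"]
print("per-1000 dyad density:", acgt["per_1000"].sum())
PY
```

Repeat per species, then `acedyad correlate` for pairwise window
statistics, `acedyad orthologs` with an ortholog table, and
`acedyad enrich` with condition gene lists. Gene identifiers must already
be consistent between the annotation, ortholog table and gene lists — no
identifier conversion is performed.

## Known limitations

- Exact matching only: no PWM or mismatch tolerance, and no reverse-strand
  scan for non-palindromic controls.
- The ATG anchor mixes promoters having long and short 5'UTRs.
- Overlapping upstream genes are not masked; a "promoter" may include
  coding sequence of a neighbouring gene.
- The enrichment screen inherits the composition of the supplied gene
  universe; regulated-gene calls from different platforms are not
  harmonized by the package.
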
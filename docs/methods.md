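# Methods

## Data model and coordinates

All internal coordinates are 1-based inclusive (the VCF convention); BED
input is converted at the read boundary and back on write, so
BED↔internal↔VCF conversions compose to identity. SV records carry one of
five types (DEL, INS, INV, DUP, TRA). For spanning types the length is
canonically `end − start + 1`; insertions are point records (`end ==
start`) whose length is the inserted-sequence length; translocations carry
a second breakend (`mate_chrom`, `mate_pos`) and no length. Negative
SVLEN on input (the common convention for deletions) is stored as its
absolute value. Multi-allelic SV records are rejected with an explicit
error: the whole analysis treats sites as biallelic deletion/non-deletion
polymorphisms. When INFO/END is absent for a spanning record, the end is
reconstructed as `POS + |SVLEN| − 1`; when both are present, END wins.
Genotypes are stored as alt-allele dosage codes (0/1/2, −1 for missing),
so a genotype matrix doubles as an allele-count matrix and frequency
estimation is a vectorised sum.

VCF parsing goes through cyvcf2 (htslib); writing is a small controlled
VCF 4.2 writer so that `read(write(x)) == x` holds field-for-field,
including genotypes, supporting-caller lists and translocation breakends
(written as `CHR2`/`END2`; delly-style `CHR2`+`END` is accepted on read).

## Consensus merging

Three rules define the merge. (1) Two spanning calls of the same type
match when their reciprocal overlap `min(O/|a|, O/|b|)` strictly exceeds
0.75; the threshold is strict because the rule is ">75%", so RO = 0.75
exactly does not match. (2) A locus is retained only when at least two
*distinct* callers support it; duplicate calls from one caller count once
toward support but all members contribute to the breakpoint medians.
(3) Consensus breakpoints are the medians of member starts and ends; for
an even member count the floor of the midpoint mean keeps coordinates
integral.

Clustering is single-linkage (connected components of the pairwise match
graph), computed within (chromosome, type) partitions by a sorted sweep
with union–find; this is the behaviour of the standard SV mergers, and
chaining across a run of partially overlapping calls is possible but
bounded by the partition and the strict threshold. The implementation is
validated against a brute-force oracle (exhaustive match matrix +
networkx connected components) on seeded random instances, and the output
is invariant to input-order permutation.

Reciprocal overlap is undefined for point-like insertions and exempted
for translocations, so both get package-defined rules: insertions match
within a 100-bp breakpoint window when the shorter/longer length ratio is
≥0.75; translocations match when both breakends lie within the same
window on the same ordered chromosome pair. Both windows and the ratio
are parameters of `MergeParams`.

Size filters run after support resolution (the ordering is a package
choice): DEL/INS kept when 50 bp < length < 10 Mb, INV/DUP when
< 10 Mb, TRA unconditionally.

## Genotypes and allele frequencies

The genotype of a site/sample is the genotype asserted by at least two
genotyping callers' member calls at that site; missing entries never count
as agreement, a single non-missing call is insufficient, and (with more
than three genotyping callers) a two-way tie at two votes is unresolvable
and yields missing. With the usual three genotyping callers a tie cannot
occur. If one caller contributed several member calls to a cluster, the
first in coordinate order is used.

Allele frequency per population is `(2·n_homalt + n_het) / (2·n_obs)`
with missing genotypes excluded from the denominator. The pooled
frequency is computed the same way over all samples of the scan
populations jointly — i.e. the sample-size-weighted combination of allele
counts, not the mean of population frequencies. A population with zero
non-missing genotypes at a site gets an undefined frequency and the site
is flagged rather than coerced.

## Selection scan

Eligible sites are deletions with length ≤ 100 kb (the "over 100 kb
removed" rule keeps the boundary), pooled frequency ≥ 0.01 (the low-
frequency cut is applied to the pooled frequency, since the per-population
frequencies are already contrasted by the statistics), and all scan
populations observed. Both statistics are computed on this one shared
filtered set:

* ΔAF = |f_focal − (f_ref1 + f_ref2 + …)/k| ∈ [0, 1]
* RFD = (f_focal − mean of references) / f_pooled, signed and positive
  exactly when the focal population is enriched.

"Mean of the references" is the arithmetic mean; any other reading would
let ΔAF exceed 1. At least two reference populations are required.

Thresholds are empirical: the cutoff is the nearest-rank 95th percentile
(the ⌈0.95·n⌉-th smallest value) and a site is flagged iff it strictly
exceeds it, so ties at the cutoff are never flagged, at most ⌊0.05·n⌋
sites pass per statistic, and the rule is reproducible without
interpolation. A site is significant only when it passes both tails;
because ΔAF is unsigned while RFD is signed, the intersection
preferentially keeps focal-*enriched* outliers and its null rate sits well
below 5% (typically 1–3% at n = 50 per population; measured against an
independent Monte-Carlo oracle in the acceptance suite).

Significant sites within `join_gap` (default 100 kb) on a chromosome are
merged into regions spanning their envelope. The joining gap is a package
parameter: region construction has no canonical definition in this kind of
discovery pipeline, and 100 kb matches the scan's length scale. Regions
are annotated with every gene whose span intersects them (closed-interval,
≥1 bp).

## SV annotation

Each SV receives exactly one class by fixed precedence
exonic > intronic > upstream_1kb > downstream_1kb > intergenic, with
"within 1 kb" measured from the gene-span boundary, strand-aware (upstream
is 5′ of the gene). The precedence matches standard region-based
annotators. BED4 gene records are treated as single-exon genes (the BED
default when block fields are absent); BED12 blocks and GFF3 exon children
give real exon structure. The class histogram is validated against a
brute-force per-SV interval-check oracle on simulated genomes.

## Synthetic data generator

The generator emulates the *downstream products* of a multi-caller WGS SV
pipeline, not reads or alignments. True SVs are placed uniformly on a
configurable genome without same-type overlap (log-uniform lengths per
type; defaults: DEL 100 bp–10 kb, INS 50–500 bp, INV/DUP 1–100 kb,
reflecting the observed dominance of sub-kilobase deletions and larger
balanced/copy events). Neutral sites draw one baseline allele frequency
uniform on [0.05, 0.95] *shared by all populations*: the exchangeable
neutral model in which any apparent differentiation is pure binomial
sampling noise. Planted "selected" sites are deletions only; they use a
configurable focal frequency (default 0.9) in the focal population and a
reference frequency (default 0.1) elsewhere. Genotypes are drawn per
sample under Hardy–Weinberg equilibrium (hom-alt f², het 2f(1−f)) — the
minimal neutral genotype model.

Callers are error profiles: a false-negative rate (default 0.2), a
caller-private uniform false-positive density (default 0.5/Mb, Poisson
count, type sampled in proportion to the configured site counts), Gaussian
breakpoint jitter independent at each end (default sd 30 bp, order
restored if inverted), and, for genotyping callers, a per-genotype error
rate (default 0). These defaults are package choices of plausible
magnitude — short-read SV callers commonly miss 10–30% of events and
disagree on breakpoints by tens of bp — and they are what the validation
suite runs under. Because false positives are drawn independently per
caller they are never shared, which is exactly the situation the ≥2-caller
support rule is designed to eliminate.

The default population layout is three populations of 50 diploids (one
focal, two references), matching the scan's intended three-breed contrast.
All randomness flows from a single seed through independent named streams
(truth / call sets / genes), so every output — including the on-disk
bundle of VCFs, population map, BED12 genes and JSON manifest — is
byte-reproducible.

What the simulations do **not** model: linkage disequilibrium between
sites, demographic history (drift makes real neutral sites more
differentiated than binomial noise, so real-data null tails are heavier),
read-level artefacts, caller error correlations (real callers sharing an
algorithm family make correlated errors, weakening the support rule), and
reference-genome structure. Passing the suite therefore demonstrates the
pipeline's correctness and calibration under its stated model, not
real-data performance.

## Numerical and scale choices

Validation experiments use 5,000-site, 150-sample simulations with 20
replicates per condition and effect sizes |Δf| ∈ {0.2, 0.4, 0.6, 0.8}
(50 planted among 5,000 neutral sites); these sizes give per-replicate
binomial standard errors of ~0.05 on frequencies, small enough to separate
every tested effect from the null. Statistic correctness is asserted to
1e-12 against hand arithmetic. Calibration and power experiments estimate
frequencies from the simulator's truth genotype matrix directly — the
statistics' behaviour does not depend on the merge stage, which is
validated separately and exactly (noise-free identity, oracle
equivalence, round-trips). Degenerate inputs are handled explicitly:
empty value lists are errors for the percentile rule, all-identical values
flag nothing, sub-20-site scans warn, unobserved populations flag the site
rather than producing NaNs, and a genome too small to host the requested
sites fails after bounded placement retries.

## Known limitations

* Single-linkage chaining can fuse long runs of mutually overlapping
  calls; the per-type partition and strict threshold bound but do not
  eliminate this.
* The scan assumes a biallelic deletion model; duplications, inversions
  and translocations are carried through merging and genotyping but never
  scanned.
* Region joining (100 kb default) is heuristic; region counts depend on
  it, gene coverage counts depend on the gene annotation's density.
* The empirical top-5% rule is a ranking, not a significance test: it
  always flags ~5% of sites per statistic regardless of whether any
  selection occurred; only the intersection's enrichment over its null
  rate is evidence.
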
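# Methods

## Scope and model

`svcohort` implements cohort-level analysis of structural variants (SVs)
called from short-read resequencing of a small case/control-structured
population. The genotype model is deliberately minimal: an SV is a cohort
event with a *carrier set* (which individuals it was detected in), not a
diploid genotype. All downstream statistics — Venn partitions, group-specific
screening, PCA, frequency tests — operate on the samples × SVs
presence/absence matrix. This matches what paired-end/split-read callers
actually deliver at low-to-moderate depth, where confident het/hom calls for
SVs are not available; "allele frequency" throughout means carrier
frequency.

## Coordinates and record types

Positions are 1-based. For DEL/DUP/INV a record satisfies `end > start` and
`length = end − start`; the affected reference bases are `(start, end]`, so
an 89 bp deletion removes 89 bases. Insertions are breakpoints
(`start == end`) whose `length` is the inserted-sequence length, absent from
the reference. Records are immutable dataclasses; merging builds new records
and never mutates its inputs, so every call preserves its coordinates
through the pipeline.

## Consensus and merging

Two quality conditions gate every call: read-pair support ≥ 3 (applied per
caller record, before matching — fail-closed: a missing support field reads
as 0 and cannot pass) and confirmation by the second caller. Two records
match when they have the same type and chromosome and their intervals
overlap by **strictly more than** 25 bp. The threshold is absolute, not
reciprocal, because it is specified in base pairs; 25 bp of overlap exactly
does not merge. Insertions have zero-width intervals, so overlap is
undefined; they match when breakpoints are ≤ 25 bp apart, reusing the same
window. Per individual, matching is greedy on the best overlap (ties:
leftmost, then smallest), which guarantees each caller record contributes to
at most one consensus call; on well-separated true variants this equals the
exhaustive maximum-overlap assignment (tested against brute force).

Cross-individual merging is single-linkage: the transitive closure of the
pairwise match relation within each (chromosome, type) bucket, computed by a
sorted sweep with union-find and verified against an O(n²) union-find oracle
in the tests. Single-linkage is order-invariant and collapses mutually
overlapping calls from different individuals into one non-redundant record.
The cluster representative is the member with the highest support (ties:
leftmost, then smallest) — averaging breakpoints would fabricate an interval
observed in no sample. Cohort filters then keep records carried by ≥ 2
individuals (counted across the whole cohort, not per group) and drop
chromosome Y, removing the influence of sex on detection.

Consensus precedes cross-individual merging (two stages rather than one
joint clustering): the quality conditions are per-individual statements, and
staging keeps the carrier count of a merged record interpretable as
"individuals with an independently confirmed call".

## Annotation

Gene models (gene → transcript → exon/CDS/UTR, read from GFF3 via gffutils)
are indexed with an interval tree. Location classes follow a fixed
precedence — `exon_intron > exon > utr > intron > upstream_downstream >
intergenic` — evaluated per transcript, keeping the most severe across
transcripts and genes; all overlapped genes are reported. The
upstream/downstream flank is 5,000 bp (configurable), the common default of
genome annotators and consistent with treating distances up to ~4.4 kb as
gene-associated. Exon/intron ordinals are strand-aware (exon 1 is 5'-most)
and rendered in the compact grammar `EXON=i/n,INTRON=j/m,STRAND=s` /
`DISTANCE=d,STRAND=s`; when an SV spans several exons the 5'-most ordinal is
reported.

Impact rules run in order per transcript: (1) DEL/DUP over a stop codon →
stop-lost, high; (2) DEL/INS/DUP contained in CDS with `length mod 3 ≠ 0` →
frameshift, high; (3) boundary-spanning or within 8 bp of a splice site →
splice-region, modifier (8 bp is the conventional splice-region window;
configurable constant); (4) UTR → modifier; (5) flank → regulatory-region,
modifier (an intentional simplification standing in for transcription-
factor-binding-site analysis); (6) intron → modifier; (7) intergenic → none.
Percentages in summary tables use exact decimal round-half-up at two
decimals.

## Group comparison

PCA column-centers the binary matrix without scaling (the encoding is
already on a common scale) and uses SVD; each component's sign is fixed by
forcing its largest-magnitude loading positive, making coordinates
deterministic and permutation-invariant. A zero-variance matrix returns zero
coordinates with a warning rather than failing.

Carrier-frequency differences use exact conditional tests with both margins
fixed: Fisher's exact test (scipy) for two groups; for three or more, an
in-repo enumeration of all tables with the observed margins under the
multivariate hypergeometric law, summing the probabilities of tables no more
probable than the observed one (the standard two-sided Fisher construction;
scipy offers no k-group version). A relative tolerance of 1e-12 guards the
`≤` comparison against floating-point ties. Reported significance defaults
to unadjusted p < 0.05; Benjamini–Hochberg adjustment is available behind a
flag.

## Enrichment and candidate screen

Over-representation is the one-tailed upper hypergeometric probability
P(X ≥ k), terms intersected with the declared background first, k = 0
reported as p = 1. No multiple-testing correction is applied by default,
matching the raw-p reporting style of the motivating analysis. The candidate
screen combines three evidence streams: (1) group-specificity, by
construction of its input; (2) membership in an enriched term (p < α) whose
*tag* marks it skin/aging-relevant — tags are lowercase word tokens of the
term name supplied in the GMT file, never hard-coded biology; (3) presence
on a curated aging-gene list. Streams 2 and 3 combine as OR: they are
alternative lines of support feeding one candidate table. The screen
reproduces the mechanical part of candidate selection only; literature-based
manual curation is out of scope.

## Synthetic study conditions

The simulator generates what the pipeline consumes, not reads: gene models,
planted SVs, and two caller-style call sets per individual. Defaults define
the study conditions:

| parameter | default | rationale |
|---|---|---|
| groups | WXP 7, XP 7, EUP 21 | the motivating cohort design |
| genome | 3 × 2 Mb autosomes + 0.4 Mb Y | large enough for ~90 spaced genes; Y exercises the chromosome filter |
| genes | 90, five 300 bp exons, 800 bp introns, 150 bp UTRs, spacing > 2 × flank | CDS always divisible by 3; flank zones never overlap neighbouring genes |
| planted SVs | 200 shared (≥ 1 carrier per group) + 40 private per group (≥ 2 carriers) + 5 on Y | private SVs with < 2 carriers would be removed by construction |
| SV lengths | log-uniform 50–2,000 bp | typical short-read SV size range |
| type mix | DEL 0.86, DUP 0.07, INS 0.06, INV 0.01 | cohort-level type proportions of the motivating study |
| location mix | intron 0.45, intergenic 0.39, flank 0.11, exon 0.03, UTR 0.01, exon–intron 0.01 | observed location distribution; every class planted at least once |
| caller noise | jitter sd 10 bp per breakpoint, FN 5%, FP 2/Mb, support ~ Poisson(8) floored at 1 | moderate short-read caller behaviour; FPs independent across callers, which is exactly the error mode the both-callers rule suppresses |

Planted footprints keep a ≥ 200 bp gap so no two true SVs are mergeable and
the truth stays unambiguous under single-linkage. Breakpoint jitter is
applied independently to both ends and the length recomputed, so caller
disagreement scales realistically with jitter. All randomness flows from one
seed through named substreams (gene models, cohort, caller A/B, gene sets),
so each stage is reproducible bite for byte.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: sequence context (repeats, GC) and alignability,
correlated caller errors, breakpoint-resolution differences between variant
classes, diploid genotypes, population structure beyond group-private
variant blocks, and length/type-dependent detection sensitivity. Recovery
rates on synthetic cohorts are an upper bound for real cohorts.

## Numerical and degenerate-input choices

Strict `> 25 bp` overlap at the boundary; deterministic tie-breaks
(leftmost, then smallest length, then sample id) everywhere a representative
or match order is chosen; natural chromosome ordering (numeric, then X, then
others); empty cohort tables refuse to write; a chromosome absent from the
gene model annotates as intergenic with a warning; a support-less caller row
is invalid rather than silently passed. The support filter keeps its role
even in "zero-noise" simulations — support is still drawn from the Poisson
law, so a private SV can legitimately drop below two confirmed carriers;
recovery there is ~98%, not 100%, and the tests assert the ≥ 90% contract
rather than perfection.

## Known limitations

Translocations are out of scope (the motivating callers do not support them
reliably). The annotator is a deliberately simplified consequence
model: no codon-level consequences, no protein predictions, no motif
scanning. The exact k-group test enumerates tables and is intended for small
cohorts (≤ ~50 samples across ≤ 4 groups); larger designs should use the BH
flag and/or chi-squared approximations from a general statistics package.
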
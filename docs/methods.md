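# Methods

## Coordinate model

All intervals are `(start, end]` on a 1-based genome: `start` is the base
preceding the affected segment (VCF POS for a symbolic SV allele), `end` the
last affected base (INFO/END), and the event length is `end − start`. This
is the only convention under which the lengths printed in the source
candidate and population tables equal `end − start` of their printed
coordinates (an HGVS-style reading `end − start + 1` would disagree with
every printed length by 1). BED input maps onto this convention without
arithmetic — internal start = BED start, internal end = BED end — which
provably preserves all overlap relations. Chromosome names are compared
after stripping a leading `chr`, so both dialects interoperate.

VCF records lacking both END and SVLEN carry no usable interval and are
skipped with a warning; breakend (BND) records are parsed and retained but
excluded from every interval operation, since one side of a junction has no
well-defined length.

## Subgroup partition

Severity is dichotomized at the third quartile of the cohort's THI
distribution with a *strict* inequality ("higher than"), so a score exactly
at Q3 is non-severe. Q3 uses linear interpolation between order statistics
(`numpy.quantile`, `method="linear"`), the common default in statistical
software; no estimator is canonical for this split, so an explicit
`thi_threshold` override is accepted to make any published cut-off (e.g. 68)
exactly reproducible. Fewer than four samples cannot support a quartile
estimate and require the override.

## Prioritization cascade

The per-caller paths are kept fully independent until the final consensus,
and each stage only removes records (the cascade is anti-monotone), which
makes the stage report's survivor counts interpretable as rejections.

- **Length filter** (default 100 000 bp, strict "greater than"): exome SV
  calls beyond this size are dominated by segmentation artifacts.
- **ACMG filter**: keeps pathogenic / likely pathogenic / uncertain.
  Classification itself is upstream (an annotation consumed from a
  configurable INFO key, default `ACMG`); records without the annotation are
  `unclassified` and are dropped by the default keep-set.
- **Sharing**: "≥ 60 % overlap in ≥ 2 samples" is implemented as
  *reciprocal* overlap — `min(I/|a|, I/|b|)` — the convention of RO-graph SV
  merging toolkits; a directional mode (`max` of the fractions) sits behind
  a config switch. Clusters are single-linkage components over edges with
  RO ≥ 0.6 *and* equal SV type, because that is what an RO-merging tool
  computes and it admits an exact brute-force oracle (the test suite
  compares against an independent all-pairs connected-components
  implementation on 500 random instances). The representative interval is
  the member-wise lower-median start/end with the majority SV type (a tied
  vote yields OTHER plus a flag); the lower median keeps representatives on
  observed breakpoints.
- **Gene annotation** is split-style — one (region, gene) row per gene
  overlapping by ≥ 1 bp — so blacklist filtering and uniqueness operate on
  rows, and a region survives as long as one row survives.
- **Severe-unique genes** are computed against the *retained non-severe
  clusters* (not raw non-severe calls): a gene privately hit by one
  non-severe sample is weak evidence against a recurrent severe region. The
  raw-call interpretation is available via `uniqueness_against:
  "raw_calls"`.
- **Consensus** across callers matches regions with RO ≥ 0.6 *or* both
  breakpoints within 200 bp. The tolerance rescues near-identical calls
  whose RO is skewed (e.g. a very small region called 50 bp apart); 200 bp
  comfortably covers the 1 bp start / 70 bp end inter-caller offsets
  observed in practice and is configurable. Matching deliberately ignores SV
  type: callers are documented to disagree on DEL vs DUP over the same
  region, and an automated pipeline must surface that conflict
  (`type_discordant`, with per-caller types recorded) rather than resolve it
  — the original analysts resolved theirs by manual read inspection. The
  consensus record carries the majority type, the union of carriers and
  genes, and the worst member ACMG class (pathogenic > likely pathogenic >
  uncertain > likely benign > benign > unclassified).

## Population and constraint annotation

A database record matches a candidate when it overlaps by ≥ 1 bp with the
same SV type; no RO threshold is applied by default because population SV
databases legitimately report partial overlaps (down to a 378 bp fragment of
a 23 kb duplication), and the point of the annotation is to show *everything*
known at the locus, sorted by descending RO. An empty match list is the
"absent from this reference population" outcome, not an error. Frequencies
are consumed verbatim — the pipeline never recomputes allele frequencies
from carrier counts, since published frequency/count columns are not always
mutually consistent. Constraint joining keeps an explicit missing marker for
unscored genes; "most constrained" means lowest LOEUF with ties broken by
highest pLI.

## Expression summarization

Each dataset is normalized by its *dataset-wide* maximum (all genes, all
tissues) to 0–100, making heterogeneous units (TPM, RPKM, microarray
intensity) comparable without assuming any cross-platform calibration; the
transform is idempotent and scale-invariant. Datasets are outer-joined by
gene symbol through an ortholog map for cross-species sources; a gene absent
from a dataset carries NaN, deliberately distinct from an observed 0. The
display transform is log10(v + 1): source heatmaps of such data include
exact zeros, and the pseudocount keeps zero fixed and the map strictly
monotone on [0, 100] (range [0, log10 101]).

## Synthetic cohort generator

The generator emulates the study conditions end to end: 310 samples, a
right-skewed THI distribution whose interpolated Q3 is pinned exactly at 68
with exactly 75 samples strictly above; three callers per sample; planted
severe-specific shared SVs (default 4) whose per-carrier, per-caller calls
are jittered uniformly by ±5 bp at the start and ±70 bp at the end
(matching the observed 1 bp/70 bp inter-caller offsets); per-(SV, caller)
dropout with probability 0.1, never reducing a planted SV below two callers;
and a 0.1 probability that one caller reports the flipped DEL/DUP type for a
planted SV. One decoy category per filter is planted (default counts in
parentheses): >100 kb oversize (2), benign-ACMG (3), blacklisted-gene-only
(3), shared-in-both-subgroups (3), non-severe-only shared (5), and
single-caller shared regions (2) that survive to — and must die at — the
consensus stage. Background private SVs (Poisson, mean 20 per sample) model
caller noise.

Design choices worth recording:

- Coordinates live on a 2 × 10 Mb mini-genome; the pipeline is
  sequence-free so no FASTA is needed. The eight genes of the published
  candidate regions are included as fixtures with synthetic stand-in
  intervals on chr7/chr12 (labelled as such in the source) so the fixture
  constraint and expression tables have real targets.
- Every planted category draws from its own mutually exclusive gene slot, so
  each decoy is rejected at exactly its designed stage and the stage report
  is assertable count-by-count.
- Background calls are placed on a non-overlapping 1 kb slot grid disjoint
  from all planted footprints. This guarantees no chance same-caller RO ≥
  0.6 clusters between background calls, which makes planted-truth recovery
  exactly scorable (precision = recall = 1 is the *designed* outcome, not a
  statistical one). Real cohorts do have recurrent artifacts that cluster;
  this generator does not model them, so a perfect recovery score validates
  the cascade's logic, not its false-positive rate on real data.
- RNG: one `numpy` substream per draw category, seeded by
  `(seed, crc32(category))`; adding a category never perturbs earlier draws,
  and a fixed seed reproduces the bundle byte-for-byte (integer coordinate
  arithmetic only).
- Carrier THI scores are forced above the threshold by drawing carriers from
  the already-severe pool, so planted truths always sit in the severe
  subgroup.

What passing the end-to-end tests shows: the cascade's filters fire at the
intended stages, breakpoint jitter and type conflicts at the observed scale
do not break sharing or consensus, and recovery bookkeeping is exact. What
it does not show: behavior under realistic caller error models (recurrent
artifacts, breakpoint errors correlated with GC or capture design, partial
calls), genome-build effects, or the published per-tool survivor counts,
whose raw inputs are access-restricted.

## Numerical and degenerate-input choices

- Lower median (not the mean) for representatives: stays on observed
  breakpoints and is translation-equivariant in integers.
- Zero-length intervals: reciprocal overlap is undefined and raises; BND and
  zero-length calls are excluded from clustering with a log message.
- All-zero expression datasets are returned unchanged with a warning
  (normalization undefined).
- Ties in the majority SV-type vote yield OTHER plus a flag at the cluster
  level; consensus type ties resolve deterministically by vote order.
- Problem sizes in the test suite: the brute-force clustering oracle runs
  500 random instances of ≤ 12 calls (exhaustive all-pairs comparison stays
  trivially cheap there); end-to-end recovery runs the full 310-sample,
  3-caller cohort across five seeds, which completes in well under a minute
  and was chosen as the smallest design that exercises every decoy category
  at full cohort scale.

## Known limitations

- The sharing step treats ACMG filtering as preceding clustering (the
  flowchart order of the source protocol); prose descriptions of such
  cascades are sometimes ambiguous on this point.
- Genotypes are parsed but unused by the cascade (the source protocol does
  not condition on zygosity).
- The expression merge requires unique gene rows per dataset; probe-level
  microarray data must be collapsed upstream.
- Published scientific-notation frequencies in the source's population table
  are typographically inconsistent; fixture tables use plausible fractions
  and the pipeline treats frequencies as opaque values throughout.
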
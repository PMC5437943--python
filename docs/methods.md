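# Methods

This note documents the models and procedures behind each `oncocohort`
module, the parameters that matter, and the deliberate design choices made
where more than one reasonable definition exists.

## Coordinate conventions

On disk the formats keep their native conventions: MAF, SEG and VCF are
1-based inclusive; gene tables (BED) are 0-based half-open. Internally
**everything** is 0-based half-open; records expose their on-disk fields
verbatim plus an `interval()` view, and conversion happens only at the I/O
boundary. Chromosome names are matched exactly — an optional `chr`-prefix
normalizer exists but is off by default, because silent aliasing of `1` and
`chr1` hides data errors more often than it fixes them.

## Interval planning

Whole-genome somatic callers parallelize naturally per chromosome, and
several of them require intact intrachromosomal context, so the planner
never splits below the chromosome level. Under that restriction the scatter
wall clock is bounded below by the longest chromosome (length *C*), which
makes *C* the natural bin capacity: any grouping whose per-group total stays
≤ *C* leaves the critical path unchanged while reducing job count and
scheduler overhead.

Packing is first-fit decreasing (FFD): chromosomes sorted by length
descending (ties broken by table order, for determinism) are placed into
the first group that still has room. FFD generalizes large/small pairing —
it reproduces exact pairing whenever only pairs fit — and is provably
*merge-maximal*: if two groups could be merged within capacity, the
later-opened group's first (largest) chromosome would have fit into the
earlier group and FFD would have put it there. The test suite additionally
checks near-optimality: on random tables with ≤ 8 chromosomes FFD's group
count is within one of the exhaustive optimum (empirically it equals the
optimum on every generated table). Groups are reported ordered by largest
member descending; within a group, chromosomes keep the input-table order.

The gather step merges per-interval sites-only VCFs: records sort by
(chromosome rank in the canonical table, position, ref, alt); exact
duplicates (same key *and* INFO) collapse; same-key records with different
INFO raise an error rather than being silently reconciled, because a
per-chromosome scatter can never legitimately produce them — a conflict
means the plan was misused.

## Ensemble consensus

Votes are counted under a normalized positional key. Normalization
uppercases both alleles, trims shared trailing bases, then trims shared
leading bases while advancing the position, stopping in both phases as soon
as either allele reaches one base (so alleles never become empty; a padded
`CAG>CG` and a minimal `CA>C` deletion meet at the same key). This is
deliberately reference-free: no FASTA left-alignment is attempted, so two
representations of the same indel inside a repeat run that differ by more
than padding will not be unified. For SNVs and simple indels — the calls
the supported callers disagree on representationally — trim normalization
is sufficient, and the toolkit stays runnable without a genome download.

`vote(results, k)` keeps keys supported by ≥ *k* callers; *k*=1 is the
union, *k*=*n* the intersection, and the output is monotonically shrinking
in *k* (all three properties are tested exactly against a brute-force
membership count). Voting is unweighted and treats SNVs and indels alike.
By default only records whose FILTER is `PASS` or `.` contribute votes
(`pass_only=True`); callers flag their own low-confidence calls, and an
ensemble should count confident ones. The consensus VCF annotates each
record with `CALLERS` (sorted, comma-joined) and `NCALLERS`.

## Cohort aggregation

**Recurrence unit.** A gene's recurrence is its number of distinct patients
with at least one protein-altering mutation, not its raw mutation count.
Distinct-patient counting is robust to hypermutated samples and is exactly
what an oncoprint row shows. Silent and noncoding classes (`Silent`, UTRs,
`Intron`, `RNA`, `IGR`) are excluded from recurrence by default
(`include_silent` reverses this); the per-cell class sets always record
every mutation regardless.

**Severity.** The worst consequence per cell follows a fixed ranking
(nonsense > frameshift > splice > nonstop > translation start > in-frame
indel > missense > silent > noncoding) with frameshift-del/ins and
in-frame-del/ins as documented tie groups; ties resolve deterministically
by enum order. The table mirrors the usual effect-predictor consequence
ordering and is passed explicitly everywhere, so a workflow that ranks
differently can substitute its own.

**Copy-number mapping.** Each (gene, patient) takes the log2 ratio of the
single overlapping segment with the largest overlap against the gene body;
overlap ties go to the segment whose thresholded state is more extreme,
then larger |log2|, then leftmost start — a single deterministic state per
gene, verified against a literal per-base tally on random segmentations.
Default thresholds on log2 ratio are (−1.0, −0.25, +0.25, +1.0) for deep
loss / loss / gain / amplification, conventional values for tumor segment
means, applied inclusively at the boundaries and fully configurable.
Genes with no overlapping segment are neutral (absence of segmentation is
not evidence of an event). GISTIC-style integer calls in {−2..2} are
accepted directly as an alternative copy-number source. Overlapping
same-sample segments are rejected as malformed input.

**Spectrum.** Only SNP records enter the six-class spectrum; purine-
reference substitutions are complemented onto the pyrimidine strand
(G>A ≡ C>T), making the counts strand-invariant by construction.
Trinucleotide context is out of scope (it needs a reference genome).

## Circos layout

The layout is gene-centric: genes below the recurrence threshold (and
blacklisted genes) are dropped, and each retained gene gets **one unit
slot** on a pseudo-chromosome whose length is its retained-gene count, in
genomic order. Equal widths were chosen over recurrence-scaled widths as
the simplest layout that preserves relative order; the threshold already
controls what is visible. The stacked SNV track reports per-class counts in
severity order — by default one count per patient, attributed to the
patient's worst class in that gene, so the stack height equals the gene's
recurrence (a `unit="mutations"` toggle counts raw records instead, summing
to the gene's mutation count). The circle track shows the total
mutated-patient count (a count, not a frequency, so cohorts of different
sizes remain comparable by eye against the stacked bars).

The three copy-number tracks per gene are: fraction of patients with a
gain-side state, fraction with a loss-side state, and the mean ordinal
state (−2..+2) across all patients. The first two are bounded in [0,1] and
insensitive to event depth; the mean restores depth at the cost of sign
cancellation — together they summarize direction, penetrance and magnitude.

Labels are bold exactly when recurrence ≥ 2× the display threshold, and
colored when the gene is on the highlight list or overlaps a user-supplied
recurrent-CNV region (both attributes can co-occur). Emission is
deterministic (sorted file order, fixed float formatting): re-emitting a
bundle is byte-identical, and `circos.conf` references every track file
exactly once.

## Oncoprint and subgroups

Genes order by descending recurrence, ties alphabetical. Samples order by
the classic mutual-exclusivity sort: each patient becomes a binary mutation
vector over the gene order and patients sort lexicographically descending
(stable, so ties keep roster order). Subgroup ordering groups patients into
ABC / GCB / U blocks, memo-sorted within each block; a caller-supplied
order is validated as a permutation and used verbatim.

Subgroup classification counts, per patient, mutated marker genes unique to
each subgroup (shared markers are dropped with a warning — a gene mutated
in both subgroups carries no signal; silent mutations do not count as
evidence). The label is the side with the larger count; equal counts —
including the zero-evidence case — yield U. Extending U from "no evidence"
to "conflicting evidence in equal measure" is the conservative reading: a
symmetric tie gives no basis to prefer either subgroup. Marker lists are
runtime inputs; per-gene significance values shown alongside the oncoprint
are consumed from a two-column TSV, never computed here.

Cells are emitted as `worst_classification|CNSTATE` (either part may be
absent; `.` for an empty cell), with burden/subgroup and
recurrence/significance covariate TSVs.

## Synthetic cohorts

The default `CohortDesign` is the study condition used throughout the
tests and the acceptance script: 50 patients on a 5-chromosome / 6.3 Mbp
toy genome carrying 52 genes (6 drivers mutated with probability 0.35–0.60,
3 + 3 subgroup markers, 40 passengers), a Poisson(40) passenger burden per
patient — so a cohort plants ≈ 2000 variants, enough for recovery-rate
estimates with sub-percent binomial error — a 40/40/20 ABC/GCB/U label
split, four recurrent CNV regions (AMP/GAIN/DEEP_LOSS/LOSS at penetrance
0.35–0.45), and three callers at sensitivity 0.9 with Poisson(4) false
positives per patient each.

Labels are planted first; marker mutations are then drawn consistently (an
ABC patient gets ≥ 1 ABC-unique marker mutation and no GCB-marker mutation,
symmetrically for GCB, none for U), and passenger mutations avoid marker
genes entirely, so on noise-free input the planted labels are recoverable
exactly — which is what the classification tests assert. False-positive
calls are drawn uniformly from intergenic space, keeping truth and FP
separable by position. Segment emission tiles every chromosome: planted
regions at state levels (±0.6 gain/loss, ±1.5 amp/deep) plus Gaussian noise
of standard deviation `noise_sd`; at `noise_sd=0` thresholding recovers the
planted states exactly. Randomness descends from one seed through spawned
seed sequences per concern (labels, per-patient mutations, per-caller
detection, segment noise), so regenerating one facet never shifts another.

Deliberately **not** emulated: read-level data, realistic mutational
signatures (the synthetic spectrum is near-uniform across the six classes,
unlike the C>T-dominated spectra of real tumors), subclonal structure, and
correlated caller errors. Passing tests therefore demonstrate the
correctness of the computations on inputs with the right shapes and planted
structure — not robustness to the failure modes of real sequencing data.

## Problem sizes and tolerances

The property suites run 500 random chromosome tables for the planner
(exhaustive optimum compared on tables with ≤ 8 chromosomes, the largest
size where enumeration stays instant), 200 random ensembles of ≤ 5 callers
× ≤ 500 variants for the consensus oracle, 100 random fixtures for the
aggregation oracles (per-base copy-state checks on 10 kb genomes with ≤ 20
segments), and the default 50-patient cohort for the end-to-end chain,
where observed truth-variant recovery must sit within three binomial
standard deviations of P(≥2 of 3 callers at 0.9) = 0.972. These sizes keep
the whole suite to a few seconds while leaving each statistical check with
comfortable power. All stochastic tests are seeded; hypothesis-based tests
run derandomized.

## Known limitations

* Key normalization without a reference cannot unify indel representations
  that differ by more than shared-base padding (e.g. alternative placements
  in long repeats).
* Max-overlap copy-state assignment reports a single state per gene; a gene
  genuinely split by a breakpoint is summarized by its majority side.
* The memo sort is the display-ordering heuristic only; no
  mutual-exclusivity statistics are computed.
* Subgroup classification is a marker count vote, not an expression-based
  classifier; its accuracy on real data depends entirely on the supplied
  marker lists.
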
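# Methods

## Candidate-region model

The pipeline treats convergent transcription as the source of nuclear
dsRNA. Because annotated 3' ends mark polyadenylation sites rather than
transcription termination, every plus-strand gene is extended 300 nt
downstream before overlap testing; the minus-strand partner is tested with
its unextended body. This asymmetric rule is deliberate: with a symmetric
windowed search each overlap is found twice (once from each gene), and
de-duplicating by keeping only plus-strand anchors makes the effective rule
"+ gene extended 300 nt downstream overlaps − gene body". A minus-strand
gene whose extension would reach a plus-strand gene — while the reverse
extension does not — is therefore *not* a candidate; the brute-force oracle
used in the tests encodes exactly this asymmetry.

The counting interval attached to a pair is the anchor's extended window
(the interval actually searched); a body-only mode is available
(`region_mode="body"`). A gene with two distinct antisense partners yields
two regions, and region counts deduplicate on the (anchor, partner) pair;
the distinct-anchor count is also reported, since either convention is a
reasonable definition of "number of candidate loci". Overlap threshold is
≥ 1 bp and chromosome-boundary clamping is silent (logged at debug level),
matching standard interval-tool behavior. Gene IDs come from the GFF3
`ID=` attribute with fallback to the raw attribute string; the annotation
source filter (default `FlyBase`) and the `parent_type` exclusion are
configurable.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED (0-based half-open) conversions happen only at I/O boundaries.

## Read reduction

Adapter trimming is exact-match suffix removal: the leftmost full-adapter
occurrence, or a terminal adapter prefix of ≥ 5 nt (`min_overlap`,
configurable). No mismatch tolerance is needed because the downstream
pipeline is exact-match throughout; reads containing N are unmappable under
exactness and are excluded from mapping and denominators.

The order of operations is fixed: size-select to 21-mers, remove reads
occurring exactly (either strand) in any transposon consensus, then map.
Uniqueness is defined over the genome only, after TE removal. Mapping uses
a hash index of every forward-strand genomic k-mer; a minus-strand hit is a
forward occurrence of the read's reverse complement, so one index covers
both strands, and for odd k (21) a read can never equal its own reverse
complement, ruling out double-counting a single locus. A read is reported
iff it has exactly one occurrence across both strands. For the TE-class
analysis, a read matching several consensi is counted for every one of
them (per-family totals, no fractional assignment).

The ppm denominator is the number of size-selected, TE-free reads with at
least one genomic occurrence (multi-mappers count once). Both this
"filtered" denominator and an all-genome-matching variant are available;
the pipeline uses the filtered one.

## Dependence classification

Expression requires reference-library ppm strictly > 5 (the floor
corresponds to ~11 reads at a ≈ 2 M-read denominator). Dependence requires
(ppm_ref + p) / (ppm_test + p) ≥ 5, where the pseudocount p defaults to the
ppm of a single read in the smaller library of the comparison. The
pseudocount keeps fully silenced loci (test ppm = 0) representable at the
top of the ranking instead of erroring; with p = 0 the plain ratio is
recovered wherever it is finite. Ratios use ppm rather than raw counts so
the two libraries' depths normalize out.

The sense fraction is defined only for loci with ≥ 10 reads in *every*
library of a comparison and is computed from a designated library
(default: the reference). The siRNA-like band is [0.2, 0.8] — "roughly
equal sense and antisense" is not a sharply defined quantity, so the band
is configurable and recorded in run metadata; sense-only loci (f = 1),
typical of structured ncRNA degradation products, are excluded. Overlap
percentages are rounded half-up to one decimal to match conventional table
formatting. A depth-matched subsampling helper (seeded down-sampling of
the deeper library) is provided as a guard against depth-driven ratio
bias, off by default.

No dispersion modeling or multiple-testing correction is applied: the
classifier is a plain ratio cutoff by design, and the tests characterize
its operating point on synthetic data (precision = recall = 1 at the
default depth, where Poisson noise is far smaller than the planted fold).

## Loading state

Retention per class is ppm_oxidized / ppm_untreated with both libraries
normalized against the *same* denominator (the untreated library's
genome-matching count). With a shared denominator, retention equals the
fraction of molecules surviving oxidation. Normalizing the oxidized
library against its own depleted denominator would instead fold the
composition shift (loss of miRNAs) into every class's retention; the shared
denominator is the contract of `retention_by_class` and the pipeline
provides it. The protection call threshold is 0.5 (inclusive),
configurable — the underlying biology is nearly binary (methylated classes
retain ≈ 1, unmethylated retain ≈ the oxidation escape rate), so the exact
threshold is uncritical.

## Binding isotherm

Because the ligand concentration (20 nM default) is not negligible against
the measured affinities (hundreds of nM), fitting uses the ligand-depletion
quadratic rather than the hyperbolic approximation. Each replicate curve is
fitted independently for (K_D, r_free, r_bound) by least squares;
replicates are summarized as mean ± sample sd, matching the conventional
"K_D = x ± y nM, n = 3" presentation. Initialization is deterministic:
K_D0 is the protein concentration nearest half-maximal anisotropy, r_free0
and r_bound0 the observed extremes. A transition smaller than 3× the noise
floor (default 0.002 anisotropy) triggers a warning; non-convergence raises
an error naming the curve. On noiseless synthetic curves the fit recovers
the generating K_D to better than 4 significant figures with residuals at
machine level.

Note the estimator's sampling behavior under the default titration design
(12-point two-fold dilution from 4000 nM): at K_D ≈ 666 nM the top point
reaches only ~85% saturation, so the plateau is weakly constrained and
single-triplicate K_D means scatter substantially with a right skew. The
acceptance script therefore averages over repeated seeded triplicate
experiments, which estimates the fitter's expectation rather than one
noise draw.

## Synthetic data

The generator emulates the features of the study system that the pipeline
exercises, with planted ground truth serialized next to every dataset and
never read by pipeline code:

- **Geometries.** Gene pairs are laid out in disjoint blocks separated by a
  spacer wider than the 3' extension: 3'-overlapping pairs (overlap
  50–300 nt), gapped pairs with the gap ≤ 280 nt (bridged by readthrough)
  or ≥ 320 nt (not bridged — these must *not* be recovered), antisense
  genes fully nested in a long host gene, and tandem same-strand controls.
  Defaults: 60/30/5/10/5, giving 100 recoverable convergent loci.
- **Duplex windows.** siRNA 21-mers are sampled uniformly from the
  intersection of each gene's body-plus-300-nt-readthrough — the interval
  where both nascent transcripts coexist — with strand Bernoulli(0.5).
  This mirrors the nascent-dsRNA model without simulating transcription
  kinetics. Sampled 21-mers are rejected and redrawn if they occur more
  than once in the genome, so planted reads survive unique-mapping.
- **Conditions.** Per-locus expected counts are base_rate (lognormal,
  σ = 0.8) × condition multiplier: dependent loci (default 20, a subset of
  recoverable loci) divided by 8 in the export-factor shutdown; every
  siRNA source (loci and TE families) divided by 10 in the dicer-null
  condition; rescue equals wild type. Libraries are multinomial draws at
  fixed depth (default 10⁶ reads), split 40/35/25% between locus siRNAs,
  TE-derived reads and miRNAs.
- **Reads.** Each insert gets the 3' adapter appended and is reported at a
  fixed raw length (34 nt), so trimming is exercised. siRNA-class reads
  carry the methylation flag, miRNA reads do not; simulated oxidation
  keeps methylated reads and unmethylated reads with probability 0.05
  (default), independently per read.
- **Determinism.** All randomness flows from `ScenarioConfig.seed` through
  per-condition seed sequences; identical seeds give byte-identical
  outputs.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequencing errors (an exact-match pipeline would
discard them; real libraries lose a depth-dependent fraction of reads),
non-uniform read coverage within loci, isoform structure and
exon/intron-resolved overlap, piRNAs and hairpin-RNA loci, adapter ligation
biases, and PCR duplication. Recovery results on synthetic data therefore
characterize the *logic* of the pipeline (filters, coordinates, ratios,
normalization), not its robustness to library-preparation artifacts.

## Problem sizes in the test suite

Unit tests run on toy fixtures and reduced scenarios (tens of loci,
20k–60k reads). The end-to-end recovery checks run the default scenario
once per session at 10⁶ reads per library; oracle-equivalence checks use
100 random annotations (≤ 200 genes) and a 200 kb genome with 550 probe
reads; Kd-recovery statistics use 100 seeded triplicates per affinity.
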
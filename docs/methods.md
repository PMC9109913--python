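# Methods

## The measurement problem

The nebulin (*NEB*) gene carries an ~30 kb segmental duplication in
which a block of eight exons is repeated three times per allele — the
triplicate (TRI) region, normally six copies per diploid genome.
Gains or losses of one block (CN 5 or 7) are benign; deviations of two
or more blocks are pathogenic. Because the three repeats are nearly
identical, unique probes cannot be designed inside them, which defeats
standard CNV callers. Droplet digital PCR sidesteps the problem: an
assay that hybridizes equally to all three repeats measures their
*summed* abundance relative to a diploid single-copy reference gene
(*EIF2C1*), duplexed in the same reaction on the FAM and HEX channels.

## Poisson quantification

A reaction is partitioned into ~20,000 nanoliter droplets. Molecule
counts per droplet are modelled Poisson; a droplet fluoresces
channel-positive iff it received at least one molecule for that
channel. From the negative fraction,

    lambda_hat = -ln(n_negative / n_total)        (copies per partition)

per channel, and the copy number per diploid genome is the doubled
rate ratio:

    CN_hat = 2 * lambda_target / lambda_ref.

The factor 2 is the reference ploidy and is a parameter
(`reference_ploidy`), so the estimator generalizes to non-diploid
references. Concentrations in copies/µL divide lambda by the droplet
volume (default 0.85 nL, the QX200 convention); the CN estimate never
depends on the volume.

**Uncertainty.** The delta method gives `var(lambda_hat) =
(e^lambda - 1)/n`. The two channels are independent under duplexing of
distinct loci (the simulator draws them independently, and empirically
the counts are uncorrelated), so on the log scale `var(log CN_hat) =
var(lambda_t)/lambda_t² + var(lambda_r)/lambda_r²`. The 95% interval is
formed with z = 1.96 on the log-ratio scale and exponentiated, which
keeps it positive and mildly asymmetric. Simulated coverage at CN 6
with 20,000 droplets is ~95% (the acceptance script recomputes it).
Edge cases: zero negatives in a channel raise a saturation error (no
finite estimate exists); zero reference-positives raise a distinct
reference-failure error; zero target-positives yield CN 0 with an
upper bound from the rule-of-three Poisson limit (3/n).

## Cluster calling

Droplets are assigned to the four quadrants (FAM±/HEX±) by per-channel
amplitude cutoffs. The boundary convention is strict: amplitude equal
to the cutoff is negative, conservative toward non-detection.
Thresholds are intended to be set manually per plate, assay, and
channel; `suggest_thresholds` provides a reproducible starting point by
1-D 2-means with deterministic initialization at the 5th/95th
percentiles (no seed needed), returning the midpoint of the recovered
centers. The separation diagnostic is the center distance in pooled
within-cluster SDs; below the floor (default 4) the suggestion is
flagged unreliable, and data where one "cluster" holds under 0.5% of
droplets with no measurable separation raise a single-cluster error
instead of returning a cutoff. Rain droplets are handled implicitly by
the threshold convention; no 2-D model-based gating is attempted.

## QC filters

Run-level removal (inclusive bounds): any single cluster with ≤ 100
accepted droplets, or total accepted droplets ≤ 10,000, or an
exclusion flag (`wga` — whole-genome amplified input, `mosaic`,
`other_cnv` — an unrelated CNV overlapping the gene). When several
rules trip, the recorded reason follows the fixed priority flags >
cluster > total so reports are deterministic. Sample-level: with two
assays in play, a sample needs at least one passing run in each.
NTC wells pass when each channel shows at most `max_positive` positive
droplets; the default of 2 is a configurable convention — instrument
practice varies and no universal rule exists.

## Replicates

Variability is summarized as %CV = 100·SD/mean. The SD uses the n−1
denominator everywhere (switchable via `ddof=0`); with duplicate pairs
this is |a−b|/√2, the spreadsheet convention. Intra-assay pairs are
same-experiment duplicates (the two highest-droplet runs when more
exist); inter-assay pairs maximize (min total, then sum of totals) over
all cross-experiment pairs, with a deterministic well-order tie-break.
The sample-level CN entering concordance is the mean of the selected
inter-assay pair (falling back to the mean of all passing runs for
single-experiment samples); a "best_run" alternative uses the single
highest-droplet run. Which aggregation real analyses use is typically
unstated, so both are exposed.

## Classification

Estimates are rounded to the nearest integer with exact .5 ties going
away from zero (spreadsheet ROUND; configurable to half-even). Away
from zero is also the conservative choice at the 7.5 boundary, where it
calls the pathogenic CN 8. Benign iff |CN − 6| ≤ 1; the normal CN and
tolerance are parameters so the rule transfers to other segmental
duplications. Composed with rounding, the benign window on the raw
estimate is [4.5, 7.5).

## Concordance statistics

Pearson correlation (t-transform p) and OLS of ddPCR CN on aCGH CN with
intercept (direction and intercept configurable; the defaults follow
the usual method-comparison plot of the new method against the
reference). Cohen's kappa is computed from the contingency table with
agreement weights w_ij — identity (unweighted), 1−|i−j|/(k−1) (linear)
or 1−((i−j)/(k−1))² (quadratic); for 2×2 tables all three coincide. The
p-value tests κ = 0 with the Fleiss–Cohen–Everitt large-sample standard
error; for 2×2 tables an exact permutation p (hypergeometric over
tables with fixed marginals) is available, and larger tables fall back
to the normal approximation. Agreement bands: ≥0.81 almost perfect,
≥0.61 substantial, ≥0.41 moderate, ≥0.21 fair, else slight (lower edges
inclusive).

**A note on the exon IV worked value.** For the published
benign/pathogenic cross-tab of the exon IV assay (cells 58, 6, 20, 14),
the standard unweighted formula gives κ = 0.352, while the figure
printed alongside that table is 0.388. The discrepancy cannot be
resolved from the published material (a different n, a correction, or a
transcription issue are all possible); this package computes and tests
the formula value and documents the difference rather than reproducing
the printed one. The exon VIII table (71, 1, 7, 19) reproduces its
printed κ = 0.774 exactly. The weighting scheme behind the published
multi-category (CN-level) weighted κ values is likewise unstated, so
both linear and quadratic variants are reported side by side and
neither is asserted against the printed figures.

## aCGH normalization

Genome-wide array normalization can leave a locus-level baseline
offset, so the *NEB* region is re-baselined locally: normalized TRI
log2 = mean(TRI probe log2) − mean(background probe log2), with
background taken from two flanking intervals inside the gene. Assuming
the normal TRI CN of 6, `CN = 6 · 2^log2`. The published breakpoints
are paired uncertainty intervals; the defaults take the outer span of
each pair (one printed coordinate pair appears in descending order and
is normalized to ascending), and the inner-span reading is available as
`AcghRegions.inner()` — probe-mean statistics are insensitive to the
handful of boundary probes either way. Probes are assigned to regions
by midpoint, unambiguous for boundary-straddling probes. Coordinates
are 1-based inclusive Hg19/GRCh37; BED input is converted on read.

## The simulator

`simulate_well` draws per-droplet target and reference occupancies
independently Poisson — the same assumptions the estimator makes, which
is the point: it provides exact ground truth for verifying the
analysis, not a physics model. Defaults are the study conditions:
20,000 droplets per well, reference rate 0.5 copies/partition (a
mid-range template load where both channels are far from saturation),
target rate `lambda_ref · CN/2`. Amplitudes are Gaussian per cluster
(FAM 1000±120 negative / 8000±400 positive; HEX 800±100 / 6000±300),
separated by >15 SDs so threshold placement is unambiguous and test
failures indict the pipeline, not the difficulty of the data. Two
departures from the ideal are available:

* **rain_fraction** — each droplet's amplitude is replaced, per
  channel and independently with this probability, by a uniform draw
  between the negative and positive means (the droplet's true occupancy
  is kept for truth bookkeeping). This is the simplest model that
  stresses thresholding; it does not reproduce the skewed rain of real
  plates.
* **linkage_fraction L** — a fraction of target molecules travels in
  indivisible 3-copy blocks (undigested tandem repeats): singles at
  rate `lambda_t(1−L)`, blocks at `lambda_t·L/3`, a block making its
  droplet positive once. The effective positive-making rate is
  `lambda_t(1−L+L/3)`, so at L = 1 and CN 6 the estimate collapses to
  2.0. This is a mechanism for exploring digestion-failure bias, not a
  claim about any particular assay's behaviour.

NTC wells are simulated with both rates zero plus an optional
false-positive droplet rate (default 0). Per-well droplet-count
variation (Normal, truncated at 1,000, defaults matching the observed
mean ~12,974 and SD ~1,701 of real plates) is available via
`draw_droplet_count` but off by default.

**What passing simulations do not show:** the generator has no PCR
efficiency differences, no inhibitors, no DNA-quality effects, no
droplet-volume variation and no cross-talk, so simulated concordance is
near-perfect by construction. Agreement statistics on simulated cohorts
validate the *statistical machinery*, not expected field performance of
a wet-lab assay.

## Problem sizes and numerical choices

Simulation studies use 100 wells per CN point for recovery checks,
1,000 wells for interval coverage, and 50 wells for the linkage
demonstration — enough for the Monte Carlo error to sit well inside the
asserted tolerances while the whole suite stays interactive. All
randomness flows through `numpy.random.default_rng` seeds;
`spawn_seeds` derives independent child seeds (< 2³¹) from one master
seed via `SeedSequence`. Results CSVs store floats at full `repr`
precision so that write→read is an exact identity.

## Known limitations

* The amplitude model is two Gaussians plus uniform rain; real droplet
  clouds are skewed with satellite clusters.
* The exact-permutation κ p-value is implemented for 2×2 tables only.
* `accepted droplets` equals all parsed droplets; instrument-side
  droplet rejection is assumed to have happened upstream of export.
* Mosaicism and CNVs extending beyond the TRI region are handled as
  input exclusion flags, not detected.
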
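# Methods

This note documents the models and procedures implemented in
`minibulkcna`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinate model

All computation happens on an ordered set of nonoverlapping genomic bins
(0-based, half-open) over chromosomes 1..22, X, Y, each carrying a GC
fraction and an optional nonnegative weight. Default bins are fixed-width
1 Mb. Published low-coverage pipelines often use "dynamic" bins whose
width varies with mappability; no mappability track ships with this
package, so the weight column stands in for that effect (a bin's expected
count scales with its weight, and zero-weight bins are masked). All
downstream mathematics is bin-width-agnostic. Chromosome names are
accepted with or without a `chr` prefix and normalized to the unprefixed
form.

## Synthetic counts: Gamma-Poisson with multiplicative GC bias

For a sample of sex *s* with injected events *E*, each bin *i* has true
copy number `cn_i` (autosomes 2; male X/Y 1; female X 2, Y 0; overwritten
by events) and expected count

    mu_i = depth * w_i * (cn_i / 2) * b(gc_i) / Z,

with `Z` normalizing so that `sum(mu) = depth`. Counts are drawn
Gamma-Poisson: `c_i ~ Poisson(Gamma(1/d, mu_i * d))`, so
`Var(c_i) = mu_i + d * mu_i^2`. The single dispersion `d >= 0` is the knob
controlling profile noise; `d = 0` is pure Poisson.

Choices and their rationale:

* **Negative binomial** is the standard over-dispersion family for
  sequencing counts; the study whose conditions this generator emulates
  characterizes its noise only through a MAPD quality cutoff, so the NB
  choice is a modelling stand-in, not a claim about the real assay.
  One consequence worth knowing: the noise sd scales with copy number, so
  high-CN regions (e.g. a CN 9.4 supergain) are proportionally noisier
  than the diploid background.
* **GC bias** is a quadratic `b(gc) = c0 + c1*(gc-0.45) + c2*(gc-0.45)^2`,
  default `(1.0, 0.4, -1.5)` — a smooth unimodal ~±10% swing over the
  generated GC range, positive on all of [0, 1]. This is exactly the bias
  shape LOWESS normalization is designed to remove; real GC bias is
  library-dependent and can be sharper.
* **Genome**: hg19-proportioned chromosome lengths tiled at 1 Mb
  (~3,093 bins at scale 1; the `scale` parameter shrinks every chromosome
  for fast tests, rejecting scales that leave any chromosome under 10
  bins, where a 5-bin minimum segment width becomes meaningless). GC per
  bin follows a seeded AR(1) process squashed into (0.3, 0.6) —
  autocorrelated like real genomic GC.
* **Default depth 1e6** mapped reads matches ~0.1× coverage binned at
  1 Mb (~324 reads/bin); at that depth the Poisson-only MAPD floor is
  ≈ 0.10, so the quality range around the 0.23 cutoff is reachable by
  dispersion alone.
* **Cohorts**: every lesional (fibrous/calcified) sample of a patient
  shares the patient's event set; normal-tissue samples are event-free.
  The OF-like menu draws chromosome-7 segmental one-copy losses and
  chromosome-12 short-arm CN-3 gains, half the time adding a focal
  supergain at CN 8.8–10; FD-like patients are event-free; OS-like
  patients receive gains/losses on ≥ 8 distinct autosomes.

`calibrate_dispersion` inverts the dispersion→MAPD map by bisection
against Monte-Carlo medians (default 20 replicates per evaluation, 5%
relative tolerance), seeding an analytic first guess from
`MAPD ≈ 1.908 * sqrt(1/mu + d)`; targets at or below the measured Poisson
floor raise an error naming the floor.

## GC normalization

`gc_normalize` fits LOWESS of (weight-adjusted) count on GC over usable
autosomal bins — sex chromosomes are excluded from the fit because a male
X or female Y would drag the curve — and evaluates the fit at every bin's
GC by interpolation of the sorted fitted curve. Counts are divided by the
fit; bins with non-positive fit or zero weight are masked; the profile is
rescaled so the median over masked-in autosomal bins is exactly 2.

* **Span 0.3, 3 robustifying iterations**: wide enough to track a smooth
  quadratic bias without bending into CNA events; the robust iterations
  damp the influence of event bins on the curve. A LOWESS `delta` of
  0.3% of the GC range makes the fit effectively O(n).
* **Median anchoring assumes a mostly-diploid genome** — true for the
  benign lesions this pipeline targets. Genomes where most of the genome
  is aberrant would be mis-anchored; that is a known limitation shared by
  every single-sample sWGS pipeline without a ploidy search.
* At least 200 usable autosomal bins are required; all-zero samples are
  rejected as empty.

Normalization is scale-equivariant (multiplying all counts by a constant
leaves the profile unchanged) and per-sample only; no panel of normals.

## MAPD and the inclusion rule

`MAPD = median(|x_{i+1} − x_i|)` over masked-in bins in genome order. For
i.i.d. Gaussian noise of sd σ, MAPD = √2 · 0.6745 · σ ≈ 0.954 σ, which is
also how the segmentation stage converts MAPD back into a noise-sd
estimate. Two conventions are configurable:

* **Cross-chromosome pairs are excluded by default**: the two bins are
  not genomic neighbours and sex-chromosome ploidy steps would inject
  signal into a noise statistic; a genome-wide flag restores the literal
  all-pairs reading.
* MAPD is computed on **linear** copy-number values, matching the printed
  definition of `x_i`; a log2 option exists for comparability with
  platforms that quote the 0.23 convention on log scale. Which scale the
  original cutoff was defined on is not stated anywhere; the default
  follows the printed formula.

A sample passes QC iff mapped reads > 100 000 **and** MAPD < 0.23, both
strict; thresholds are configurable. QC failure is recorded, never fatal,
and never drives a nonzero exit code.

## Circular binary segmentation

Per chromosome, over masked-in bins: all arcs (i, j) of the circularized
sequence — equivalently all windows x[i:j] with
`min_width <= j−i <= n−min_width` — are scanned with the two-sample
statistic comparing the mean inside against outside. Since permutations
preserve the value multiset, the pooled-variance factor of the t statistic
is constant within a scan and cancels; the implementation maximizes
`|sum(x[i:j]) − k·mean(x)·| / sqrt(k(n−k))`. The maximum is referred to
its permutation null (default 1000 seeded shuffles, early-stopping as soon
as the exceedance count guarantees p > alpha); a change is declared when
p ≤ alpha (default 0.1), the segment is split at i and j, and the pieces
are recursed. Ties in the maximal statistic break toward the smallest
(i, j) lexicographically, for determinism.

After convergence, **undo splits**: the adjacent pair of segments whose
means differ least is merged while that difference is below
`undo_sd × sd_est` (default `undo_sd = 0.1`), with means recomputed after
each merge. `sd_est = MAPD / (√2 · 0.6745)` — the MAPD-derived noise
scale; the reference implementation this parameterization mirrors does
not specify its estimator, so this is the package's documented choice.

Numerical/degenerate-input rules: chromosomes with fewer than
`2·min_width` masked-in bins form one untested segment; empty chromosomes
contribute none; segment means are always recomputed from the member
values (in the optional log2 mode, means are back-transformed as
`2·2^mean`). Segmentation runs on linear CN by default, consistent with
the linear calling thresholds; the log2 mode exists for parity with common
practice elsewhere.

**Expected behaviour at alpha = 0.1**: the permutation test's size means
roughly 10% of genuinely flat chromosomes acquire a spurious split (the
false-positive experiment below measures ≈ 11–13% over 200 null
chromosomes, within its ≤ 15% budget), and occasionally a split lands
inside a true event where copy-number-scaled noise produces real local
structure. Downstream consumers should therefore treat contiguous
same-direction calls as one CNA region; `merge_adjacent_calls` does
exactly that with a length-weighted mean.

An exhaustive dynamic-programming least-squares partitioner
(`oracle_segment`, n ≤ 200, ≤ 4 segments) serves as the independent
reference: on seeded single-step instances (ΔCN 1.0, noise sd 0.1, 100
bins) the CBS boundary matches the oracle's within ±1 bin in ≥ 48/50
instances, and in measured runs in 50/50.

## CNAscore and calling

Per chromosome: jump term = mean |s_i − s_{i−1}| over successive segment
pairs (0 with fewer than two segments); deviation term =
0.5·|mean(s_i) − norm| with `norm` from the sex-aware ploidy table. The
total sums the chromosomes present; absent chromosomes (e.g. the female Y
when masked) contribute 0.

* `mean(s_i)` is the **unweighted** mean over segments — the literal
  reading of the formula. A length-weighted option is provided because a
  5-bin supergain otherwise carries the same weight as a whole-chromosome
  segment (the worked example in the README shows how strongly a
  supergain inflates the unweighted score); the unweighted form remains
  the default.
* Calling uses strict thresholds per ploidy class (diploid 2.4/1.7,
  haploid 1.5/0.5); `norm = 0` chromosomes are never called; segments
  shorter than `min_call_bins` (default = `min_width` = 5) are below
  calling resolution.
* A sample is CNA-positive iff it has ≥ 1 call. A patient is positive iff
  ≥ `min_positive_samples` of their QC-passed lesional samples are
  positive (default 1; normal-tissue samples never count). Patients with
  zero QC-passed lesional samples are *indeterminate*, reported
  distinctly. How patient-level positivity should aggregate over a
  patient's many samples is genuinely open; the parameter is exposed
  rather than fixed.

## Cohort aggregation

* **Recurrence tracks**: per bin, the fraction of samples whose gain
  (resp. loss) calls cover the bin, over a caller-supplied denominator —
  by default the QC-passed lesional samples. A patient-level denominator
  is a caller choice (pass one sample per patient).
* **Smallest common region**: on one chromosome and direction, interval
  endpoints are swept; between consecutive endpoints the covering patient
  set is constant; maximal runs with a constant set are candidates and
  the largest set (≥ 2 patients) wins, ties toward the widest region.
  The result is contained in every supporting patient's interval by
  construction.
* **Concordance**: direction-matched Jaccard index over altered bins;
  two CNA-free samples are defined fully concordant (flagged
  "both-negative" on request). The underlying notion of "identical CNA
  pattern" is qualitative in the source material; the Jaccard metric plus
  a 0.8 "consistent" threshold operationalizes it, both configurable.
* **Score distributions**: per group n/min/median/max and the fraction
  above a cutoff that defaults to the maximum score of the normal group,
  recomputed from the data at hand, never hard-coded.
* **Diagnostic flags** are decision support only: CNA positivity,
  chromosome-7/12 involvement, and a complexity warning (calls on ≥ 8
  distinct chromosomes, or median CNAscore above an optional cutoff —
  the ≥ 8 rule mirrors the observation that osteosarcoma-like genomes
  carry breakpoints on 9+ chromosomes, and is configuration, not a
  clinical claim). Labels always state that absent CNAs do not exclude
  any diagnosis.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

All experiments generate their data at run time from seeds. Problem sizes:
50 step instances for the oracle comparison; 200 null chromosomes for the
false-positive rate; 100 replicates for event recovery; 20 replicates per
calibration evaluation; a 6-patient cohort (3 OF-like, 3 FD-like; one
fibrous, one calcified, one normal sample each) for end-to-end recovery.

Event recovery is judged per event on (1) segmentation boundaries at both
event edges within ±1 bin, (2) length-weighted mean CN over the event
within 0.15 copies (0.5 for the supergain, whose copy-number-scaled noise
is proportionally larger), and (3) all overlapping calls having the
correct direction — segmentation accuracy and calling correctness are
assessed separately rather than requiring one call to span the event,
because statistically real sub-splits inside an event fragment it without
moving its edges.

In the cohort experiment, patient-level status requires the CNA pattern in
**both** lesional samples (`min_positive_samples = 2`). Rationale: a
patient-level CNA verdict in the multi-sample microdissection design this
emulates rests on patterns consistent across a patient's samples, and at
alpha = 0.1 a marginal single-sample false call (measured ≈ 0.3% per null
chromosome) would otherwise flip an event-free patient's status in a
noticeable fraction of cohorts. The package-wide default remains 1.

What passing does and does not show: the generator's Gamma-Poisson noise,
quadratic GC bias and clean event boundaries are idealizations. Real
minibulk libraries add waviness from mappability and replication timing,
GC bias of library-specific shape, duplicate structure, and admixture of
non-lesional cells that attenuates event amplitudes. Passing these
experiments demonstrates correctness of the algorithms under the stated
noise model — not calibrated performance on real sequencing data.

## Known limitations

* Single-sample normalization with a diploid median anchor; no
  purity/ploidy deconvolution, no integer-CN genotyping.
* CBS false-split rate is alpha by construction; callers wanting fewer
  fragments should lower alpha or raise `undo_sd` rather than post-filter.
* The smallest-common-region sweep treats each patient's calls as given;
  it does not model uncertainty in boundary placement.
* BAM input is not parsed; the pipeline starts from mapped-read positions
  (text) or a bin count matrix.
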
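# Methods

## Poisson quantification of droplet wells

A ddPCR reaction is partitioned into N droplets of volume v. Template
molecules load droplets as a Poisson process with mean λ copies per
droplet, so each droplet is positive with probability 1 − e^(−λ).
Observing k positives gives the maximum-likelihood estimate
λ̂ = −ln(1 − k/N) and concentration c = λ̂/v in copies/µl.

Defaults: v = 0.00085 µl (0.85 nl, the droplet volume of the instrument
family used for the BRAF assays; overridable everywhere), N = 20 000. A
fully positive well (k = N) raises a saturation error instead of silently
applying a continuity correction: saturation means the sample must be
diluted and re-run, and hiding that would mask assay failure. Replicate
wells of the same assay may be pooled by summing per-channel counts
(`merge_wells`) before estimation, which is the statistically exact way to
tighten the estimate.

The variance of λ̂ is (e^λ − 1)/N (delta method on the binomial), minimized
near λ ≈ 1.59; both default loadings in the simulator sit in the efficient
λ ≈ 0.2–1.7 range.

## Confidence intervals

All intervals are parametric bootstrap: resample k* ~ Binomial(N, k/N)
(jointly across both duplex channels for TCF), re-apply the estimator, and
take empirical quantiles (default 2000 replicates, 95% level). A seed is
mandatory — there is no implicit global randomness anywhere in the package
— so identical inputs and seed give identical intervals. The bootstrap was
chosen over a delta-method interval because the same machinery serves the
plain concentration, the copy-number ratio and the nonlinear allele-ratio
transform without case-by-case derivations, and it respects the [0, 1]
support of TCF after clamping.

## TCF estimators

Tumor genomes carry 3 copies of BRAF exon 14 against 2 copies of the
exon-3 reference, and one mutant plus one wild-type V600E allele; normal
(microenvironmental) genomes carry 2/2 and 0/2. For a mixture with tumor
fraction f:

- duplication assay: CN = 2·c₁₄/c₃ = 2 + f, so **f = CN − 2**;
- mutation assay: r = c_mut/c_wt = f/(2 − f), so **f = 2r/(1 + r)**.

Both estimators clamp to [0, 1] and set `clamped_flag` when the raw value
falls outside — droplet noise can push CN slightly below 2 or above 3, and
r > 1 is impossible under heterozygosity — so noisy wells stay analyzable
but auditable. The mutation estimator assumes exact heterozygosity and
diploidy at the V600E locus; no copy-number adjustment of the allele
fraction is attempted. The duplication assay treats any exon-14 copy gain
(KIAA1549:BRAF fusion or plain duplication) identically.

A precision asymmetry worth knowing: at N = 20 000 the allele-ratio
(mutation) assay estimates f with a standard error of roughly 0.004–0.013
across the 0.2–0.95 range, while the copy-number (duplication) assay's
standard error is ~0.032 at any loading, because the signal is a ratio of
two concentrations whose informative difference is at most 50% of the
reference. A single-well duplication measurement therefore recovers f to
±0.05 only ~88% of the time (the closed-form delta-method ceiling, which
the test suite checks the simulation against); reaching ±0.05 at 95%
confidence with the duplication assay requires pooling roughly two wells.

## Cohort table

The packaged reference table (`ddtcf/data/cohort_table1.tsv`, 18 pLGG
samples) is the documented TSV schema: sample_id, sex, age_years,
histology, localization, methylation_class, classifier_score, alteration,
detection_method; "NA" marks an absent score and "Not done" /
"Not classifiable" are methylation sentinels. Alteration strings are
normalized case-insensitively and tolerate punctuation variants
("KIAA1549:BRAF-fusion"). Samples are ddPCR-trackable when the alteration
is the fusion, a duplication or V600E; the three samples with other
alterations (a 599TT insertion and two atypical fusions) cannot be
monitored. Localizations are grouped supratentorial / infratentorial via a
documented lookup (posterior fossa, cerebellum, brain stem, midbrain →
infratentorial; parieto-occipital, temporal, optic pathway →
supratentorial); spinal is anatomically neither and forms its own "other"
bucket. Whether a PRKAR2B:BRAF fusion would present a detectable exon-14
gain is unknown; it is counted non-trackable.

## Trajectories and outcome calls

Each sample is split into an astrocyte-basal-medium (ABM) and a neural
stem-cell-medium (NSM) arm and measured at up to four stages: p0 (initial
suspension, before seeding — its medium is NONE), p1 (≈1 week), transduced
(first passage after successful SV40-TAg infection) and final. Milestones
form a monotone chain (line established ⇒ transduced ⇒ viable at p1),
enforced as an invariant. The relative p0→p1 change is defined as
(f₁ − f₀)/f₀ — difference over baseline — chosen over a log-ratio for
interpretability as fractional growth; it is undefined at f₀ = 0.

`classify_outcome` looks only at the FINAL TCF and the milestones:
ESTABLISHED requires transduction plus final TCF ≥ 0.95, FAILED requires
final TCF ≤ 0.05, everything between is INDETERMINATE. The 0.95/0.05 bands
(config-overridable) stand in for the exactly-100%/0% terminal states real
cultures reach, leaving room for measurement noise. An untransduced culture
with a final measurement is classified (FAILED or INDETERMINATE) but can
never be ESTABLISHED, since no line ever arose without transduction; this
keeps milestone tables defined over whole cohorts.

## Statistics

The statistics layer wraps scipy.stats behind validated interfaces:
Welch's unequal-variance t-test (the default unpaired test of the R stats
package this analysis style follows; the pooled variant is available via
the F = t² identity check only), one-way ANOVA with Tukey's HSD
(studentized-range adjusted p-values), Pearson correlation, and
five-number boxplot summaries with linear-interpolation quantiles (R type
7), fixed for reproducibility. The test suite cross-checks these against
independently frozen oracles: R 4.3.3 for t/ANOVA/Pearson and a direct
numerical integration of the studentized-range CDF (quadrature error
< 1e−13) for Tukey, since R's `ptukey` approximation itself is only
accurate to ~3e−6.

## Synthetic data generator

The generator emulates the study conditions layer by layer:

- **Mixtures**: exact expected concentrations from the genome copy model
  above, at a default loading of 1000 cell-equivalents/µl (≈3 ng/µl gDNA,
  a routine ddPCR input putting both channels in the efficient λ range).
- **Droplets**: positives ~ Binomial(N, 1 − e^(−c·v)) per channel,
  independent across channels (fragmented templates partition
  independently).
- **Growth competition**: a discrete replicator map
  f′ = f·wT / (f·wT + (1 − f)·wE) with per-passage fitness multipliers —
  the simplest model with the observed bimodal endpoints: unless wT = wE
  exactly, every trajectory converges monotonically to 0 or 1. SV40-TAg
  transduction multiplies wT by a boost (default 1.2) from the transduction
  passage (default 2) onward.
- **Cohorts**: ages ~ Normal(7.9, 5.4) truncated at 0 years; initial TCF
  ~ Normal(0.55, 0.23) truncated to [0.20, 0.95]; alteration frequencies
  11 : 3 : 1 : 3 (fusion : V600E : duplication : other); viability at p1
  with probability 17/18; transduction success 10/17 in ABM and 0 in NSM.
  Tumor fitness is linked to age as wT = 1.15 − 0.06·age + ε,
  ε ~ Normal(0, 0.05), floored at 0.5, with wE = 1 and 60 passages. These
  constants were fixed once so that the establishment age threshold
  (≈5 years), the established fraction among transduced cultures (≈20–30%)
  and the negative age/TCF-change correlation match the qualitative
  structure of real cohorts; they are configuration, not biological claims.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning (one substream per sample), so cohort runs are bit-reproducible
and insensitive to evaluation order.

What the generator does **not** emulate: droplet "rain" (intermediate
fluorescence) and gating error, PCR inhibition, gDNA fragmentation-length
effects, subclonal tumor populations, aneuploidy at the V600E locus,
senescence dynamics beyond a constant fitness multiplier, and transduction
efficiency as anything richer than a Bernoulli event plus a fitness boost.
Passing tests therefore validate the estimators and the analysis logic
under the stated partition model, not the wet-lab behavior of any
particular assay.

## Numerical choices and degenerate inputs

λ̂ uses `log1p` for accuracy at low occupancy; k = 0 returns exactly 0 with
a degenerate [0, 0] interval. Bootstrap resamples that saturate (k* = N,
vanishingly rare for k < N) are capped at N − 1; resamples with an empty
reference channel are dropped from the TCF bootstrap. Zero reference
concentration raises (no denominator), as does a zero wild-type signal
with mutant present (outside the heterozygous model). Quantiles,
thresholds and tie-breaks are all inclusive (≥ success, ≤ failure).

## Problem sizes

Simulation-based checks use 200 replicates per point on a 16-point TCF
grid at 20 000 droplets for recovery, 500 wells × 2000 bootstrap
replicates for CI coverage, and 60–200-sample cohorts for trajectory and
correlation properties — sizes at which the binomial sampling error of
each estimated rate is well below the margins being asserted, while the
whole suite still runs in seconds.

## Known limitations

- Absolute study values (per-well droplet counts, per-sample trajectories)
  were never deposited, so the package reproduces formulas, counts and
  structural properties, not the original concentration tables.
- The duplication-assay TCF is written here as CN − 2; the source
  description prints the sign flipped, which is inconsistent with its own
  premises (tumor CN 3, normal CN 2, mixtures in between) and is treated
  as a typographical error.
- TCF from fusion breakpoint assays other than the exon-14 proxy, tumor
  subclonality, and A2B5 selection effects are out of scope.
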
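# Methods

`fgmtools` implements a complete fecal glucocorticoid metabolite (FGM)
workflow for competitive enzyme immunoassays (EIA): plate quantification
with four-parameter logistic (4PL) standard curves and a duplicate-CV
quality-control cascade; analytical validation (parallelism and
spike-recovery accuracy); and per-individual longitudinal analysis —
baseline estimation by SD trimming, peak detection, dual-metabolite
stress-event classification, and husbandry-note matching. A synthetic-data
generator provides ground truth for every stage.

## Plate model and percent bound

A 96-well competitive EIA plate carries, each in duplicate: non-specific
binding (NSB), total activity (TA), zero-standard blank, and maximum
binding (B0) control wells, a full standard ladder (seven two-fold
standards 156–10,000 pg/mL for the cortisol kit, five five-fold standards
32–20,000 pg/mL for the corticosterone kit), and samples. Optical densities
at 405 nm are transformed to percent antibody bound,

    %B = 100 · (OD − NSB̄) / (B0̄ − NSB̄),

anchored by the duplicate means of the NSB and B0 wells. TA and blank wells
are validated for presence but enter no computation (they are kit
controls). The blank is not used as an additional %B anchor; NSB/B0
anchoring is the kit-standard definition, and the alternative would only
rescale the zero-dose end.

Duplicate agreement is scored as CV% = 100·SD/mean of the two ODs, with the
sample SD (n−1 denominator; this convention is used for every SD in the
package). A duplicate passes at CV strictly below 10%. CVs are computed on
ODs, not back-calculated concentrations, because re-run decisions happen at
the plate stage before quantification.

## Standard curves

The dose–response model is the 4PL

    y(x) = d + (a − d) / (1 + (x/c)^b),

with `a` the zero-dose response, `d` the infinite-dose response, `c` the
inflection concentration (EC50, pg/mL), and `b` the slope factor; in a
competitive assay the response falls with dose (a > d, b > 0). Curves are
fit by unweighted least squares on duplicate-mean %B, deterministically
(initializer: a = max response, d = min response, c = geometric mean of the
doses, b = 1; a fixed fallback grid of starts if the first attempt fails —
no random restarts).

Because the %B transform is definitionally anchored — 100 at zero dose, 0
at infinite dose — the default fit fixes a = 100 and d = 0 and estimates
only (b, c), the classical constrained B/B0 fit long used in RIA/EIA
work-ups (it is the 4PL analogue of the logit-log method). This matters on
short ladders: with seven points and 5% multiplicative response noise, a
free 4-parameter fit leaves the EC50 poorly identified (the zero-dose
asymptote is never observed, so `a` and `c` trade off; simulation puts the
median EC50 error near 20–30% even for multi-start and likelihood-based
fits), while the anchored fit keeps the median EC50 error under 5%.
`asymptotes="free"` restores the full 4-parameter fit for OD-space or
otherwise un-normalised responses.

Back-calculation uses the closed-form inverse

    x(y) = c · ((a − d)/(y − d) − 1)^(1/b),

valid for responses strictly between the asymptotes. Responses beyond the
high-dose asymptote signal ABOVE_CURVE (the sample is too concentrated:
redilute and re-run); beyond the zero-dose side, BELOW_CURVE (route to
below-detection imputation). The same signals apply when the inverted
concentration falls outside the calibrated standard range, whose lower end
is treated as the assay's minimum detection limit.

## Quantification and QC cascade

Final concentrations are expressed per gram of dry feces:

    C_fecal (ng/g) = C_extract (ng/mL) · D · V / m,

with D the sample dilution factor (1:10 cortisol, 1:30 corticosterone by
default, overridable per sample for re-runs), V the solvent volume (2 mL)
and m the dry extraction mass (target 0.20 ± 0.02 g). Extractions below
0.18 g — the lower bound of the target window — are discarded
(MASS_DISCARD); masses above the window are accepted and corrected by the
mass term.

The QC cascade: a sample duplicate with CV ≥ 10% is flagged for re-run on
another plate; a failing standard duplicate, or more than 50% of sample
duplicates failing, forces a whole-plate re-run. Intra-assay CV is
operationalized as the mean sample-duplicate CV within a plate (threshold
10%); inter-assay CV as the CV of a pooled control sample quantified across
plates (threshold 16%) — the thresholds are stated by the workflow, the
formulas are this package's operationalization. The latest usable
measurement per (sample, assay) supersedes earlier flagged ones; the full
audit trail is retained.

Samples below the lowest standard are assigned the midpoint between zero
and that standard, converted by the extraction ratio alone:
0.5 · 0.156 ng/mL · (2 mL / 0.2 g) = **0.78 ng/g** for cortisol and
0.5 · 0.032 · 10 = **0.16 ng/g** for corticosterone. Note the deliberate
omission of the dilution factor, which reproduces the conventional printed
constants; a dilution-corrected cortisol value would be 7.8 ng/g, and a
config switch (`bld_include_dilution`) exposes that alternative.

## Analytical validation

**Parallelism.** Standards and a serially diluted sample pool (neat, 1:2 …
1:64) are fit as straight lines in (log10 dose, %B); the pool's dose proxy
is 1/dilution, since only relative dose matters for slope comparison. Only
points with %B in [20, 80] enter the fits (the logistic tails break
linearity; the window is configurable). Slope equality is tested by the
extra-sum-of-squares ANCOVA F test for the dose×series interaction in the
two-line model, df = (1, n − 4), at α = 0.05; when both lines fit exactly
the statistic is taken as F = 0 (no evidence of non-parallelism) rather
than the indeterminate 0/0. The pool's 50%-binding dilution is found by
linear interpolation in (dilution factor, %B) between the two bracketing
points — e.g. 55 %B at 1:4 and 45 %B at 1:8 interpolate to 1:6 — and the
working dilution is max(50%-binding dilution, floor), with a 1:10 floor
against methanol matrix interference.

**Accuracy.** Standards spiked with a fecal-extract pool are regressed
(OLS) as observed against expected concentration, the expected values being
the standards after subtracting the known spike contribution. Acceptance
requires r² > 0.95 and slope in [0.8, 1.2].

## Longitudinal analysis

Per animal and metabolite, multiple samples on one calendar day are
averaged into a daily value first. The untrimmed mean μ and sample SD σ are
computed over the whole series; the **baseline** is the mean after a single
pass removing values above μ + 1σ (an iterate-to-convergence variant sits
behind a flag). **Peaks** use the untrimmed statistics: a daily value is a
peak when it strictly exceeds μ + 2σ — ties are not peaks, and a constant
series has none. A consequence of the (n−1)/√n bound on the maximum
z-score is that for n ≤ 5 a single outlier can never reach 2 SD.

An adrenal **stress event** requires both metabolites to peak on the same
sampled date (single-assay exceedances are discounted because the
antibodies cross-react). Dual-peak dates adjacent in the animal's sampled
sequence and at most 7 calendar days apart (configurable) group into one
event: one date = acute, a run = chronic. Events are matched against
husbandry notes on the peak day or the preceding calendar day — a 48-hour
lookback applied at day resolution, since fecal timestamps are collection
times, not excretion times. The study summary reports per-animal baselines,
per-metabolite peak counts, dual-peak counts and note-associated dual-peak
counts, plus study totals and the percent of dual peaks with notes.

## Synthetic data

The generator emulates the structure of a long-term, opportunistically
sampled captive study:

- **Plates**: ODs follow the 4PL between a B0 OD of 1.0 and an NSB OD of
  0.05 with the EC50 at the geometric mid of the ladder, under
  multiplicative lognormal noise of configurable CV (default 5% per well in
  the CLI, 0 in unit fixtures). Ground-truth in-well concentrations are
  recorded for every sample.
- **Series**: per-animal lognormal baselines (defaults: cortisol
  ln-mean ln 30, corticosterone ln 65, ln-SD 0.5 — medians in the tens of
  ng/g with moderate right skew, as FGM data are positive and skewed).
  The default roster has four animals with 233/122/72/60 samples drawn
  without replacement from each animal's span at ~2 samples/week. Spikes
  are added to both metabolites in units of the animal's linear-scale SD
  (default 6σ) with lognormal height jitter (ln-SD 0.1) correlated ρ = 0.9
  between metabolites; default acute spike counts are 11/0/5/7. Values
  below the working-dilution detection floor are censored to the assay's
  BLD constant. A ledger records every injected event; sensitivity is
  always scored against the ledger, never against re-detected events.
- **Notes**: emitted within the 48-h window for 39% of injected events
  (configurable), plus random decoy notes (~1 per 100 days).

What the generator does **not** emulate: circadian and seasonal structure,
gut-transit delay between stressor and excretion, assay drift across years,
cross-reactivity between metabolites beyond the spike correlation, and
autocorrelated baselines. Passing tests therefore demonstrate the
pipeline's correctness and detection behavior under the stated model, not
performance on real series with those features.

## Numerical choices and problem sizes

- Sample SD (ddof = 1) everywhere; SD of a length-1 series is 0.
- Strict inequalities at every threshold (<10% CV pass, >2SD peaks).
- CSV floats are parsed with round-trip precision so plate files re-write
  bit-identically; fixed seeds make the simulate→quantify→longitudinal
  chain byte-deterministic.
- Statistical test sizes used by the suite: 200 replicate curve fits at 5%
  noise; 1000 parallelism replicates for the type-I rate (expected
  0.05 ± 0.02) and 500 for power; 10,000 random series for the baseline
  bound; a 10×1000-sample null study for the dual-peak false-positive rate
  (≤0.5%) and a 20×100-sample study with two 5σ acute spikes per animal
  (ρ = 1) for sensitivity (≥95%). These sizes keep every check
  well-resolved while the whole suite runs in seconds.

## Known limitations

- The anchored %B fit assumes the transform's anchors are trustworthy; a
  plate with a drifting B0 biases all concentrations on it.
- The inter-assay CV requires a pooled control to be run across plates; it
  is reported as unavailable otherwise.
- Event classification operates at day resolution; multiple distinct
  stressors within one day merge.
- Baselines and peak thresholds are per-individual constants; no trend,
  season, or age adjustment is attempted.
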
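# Methods

## Problem and scope

After severe traumatic brain injury, EEG reactivity to external
stimulation is a candidate bedside marker of preserved sensory processing
and of eventual recovery from coma.  The analysis implemented here takes
multichannel EEG recorded at rest and during four types of tactile
stimulation (soft/hard brush × slow/fast stroking, 10 trials of 10 s
each), estimates spectral power in unit-width frequency bins from 2 to
20 Hz, and asks three questions:

1. **Group level** — do patients differ from controls in resting band
   power, and does stimulation change band power (mixed 2 GROUP × 5
   CONDITIONS repeated-measures ANOVA on electrode-averaged power)?
2. **Individual level** — per subject and electrode, is the band power of
   the 40 stimulation trials shifted relative to 40 rest fragments
   (two-sample rank test, Bonferroni across the 19 electrodes,
   0.05/19 ≈ 0.0026)?
3. **Brain-structure level** — across patients, is the electrode-wise
   band-power contrast (stimulation − rest) rank-correlated with
   morphometric covariates (whole-brain gray-matter volume, right putamen
   and insula volumes, surface-hole count as a damage proxy, cortical
   thickness) and with the coma outcome (GOSe)?  Inference uses a
   cluster-based permutation procedure.

Raw patient data are not available, so the package ships a synthetic
cohort generator whose statistical structure matches the study design;
every stage is exercised end to end against it.

## Spectral estimation

PSD is FFT-based: Welch averaging of 2-s Hann-tapered segments with 50%
overlap inside each 10-s epoch.  A single full-epoch rectangular window
(plain periodogram) is retained as a first-class mode; it is the mode the
oracle tests pin to a direct DFT computation at 1e-9 relative error.
Condition spectra are the mean of per-epoch raw spectra (equal in
expectation to concatenating epochs, but robust to inter-trial
discontinuities), then normalized per electrode to relative power over
[2, 20) Hz, then integrated over the 18 half-open unit bins
[2,3), …, [19,20) by trapezoidal quadrature.  The bins of a normalized
spectrum sum to 1 by construction; pass-through (no normalization) is
selectable.

Band schemes: the contrast scheme (theta 4–6, alpha 11–13, beta
17–20 Hz) and the resting-comparison scheme (alpha 8–12, beta 16–20 Hz)
are both shipped; neither is silently preferred, the pipeline
configuration chooses.  "Slow" is 2–6 Hz in both.

A taper trade-off worth knowing: with 2-s Hann segments the mainlobe of a
pure tone spreads into the two adjacent unit bins (≈83% stays in the
tone's own bin); the full-epoch periodogram resolves the same tone to
>99%.  Welch remains the default because per-epoch variance, not bias,
dominates the band statistics used here.

## Rank statistics

Mann–Whitney U (morphometry group comparisons) and the two-sample rank
test on per-trial band powers use midrank ties, exact enumeration for
small tie-free samples, and the normal approximation with tie and
continuity corrections otherwise.  The stimulation trials and rest
fragments are not naturally paired, so the per-subject test is the
unpaired rank-sum form; a paired signed-rank mode exists.  The mixed
ANOVA uses the classical split-plot sums of squares (between factor
tested against subjects-within-groups, within factor and interaction
against the condition × subject error), no sphericity correction by
default (Greenhouse–Geisser optional), and reports F, df, MS and p;
degrees of freedom always derive from the data.

## Cluster-based permutation procedure

Per electrode, Spearman's rho between the patient contrast map and a
scalar covariate is converted to t = ρ√((n−2)/(1−ρ²)).  The map is
thresholded at the 2.5th/97.5th quantiles of the permutation t values
pooled over electrodes and permutations (a parametric t(n−2) threshold is
available), supra-threshold electrodes are grouped into sign-separated
connected components on a fixed 10-20 adjacency graph (plain-text edge
list shipped with the package; e.g. C3 ~ {F3, T3, Cz, P3}; minimum
cluster size 1, so singletons survive), and each cluster is scored by its
mass, the sum of member t values.  The null distribution is the maximum
absolute cluster mass over N = 500 random permutations of the covariate
across subjects; the max-statistic construction gives weak family-wise
error control for the two-sided test.  Cluster p uses the add-one
estimator (b+1)/(N+1), whose floor at N = 500 displays as 0.002.
Bonferroni across the covariate battery is applied by default.  The
permutation RNG is seeded and the permutation matrix can be retained for
exact replay.

## Synthetic cohort

Each epoch is a sum of Gaussian processes synthesized in the frequency
domain: a 1/f background (exponent 1.0) plus band-limited components
whose spectral envelope is the squared magnitude response of a 4th-order
Butterworth band-pass — the spectrum of zero-phase (forward–backward)
filtered noise, generated without the filtering cost.  Component powers
are calibrated so the mean periodogram band power equals the target
(verified to 10% over 100 epochs by an independent periodogram oracle).

Defaults (rest, µV² per component band): controls delta 10, theta 10,
alpha 40, beta 10; patients delta 45, theta 40, alpha 12, beta 5;
background 110 µV² over 2–20 Hz, making the control resting alpha SNR
roughly 2.  These give patients clearly elevated 2–6 Hz and reduced
alpha/beta relative power at study-scale n (the group rank tests reject
at p < 0.01), without being trivial per epoch.

Stimulation multiplies each patient's theta component by (1 − d), where
the latent suppression d is Uniform(0.15, 0.65) via a probit transform of
a standard-normal subject latent; controls have d = 0.  Stimulation also
multiplies alpha/beta component power by 1.15 in both groups.  That gain
is deliberately modest: band powers are analysed as *relative* power, so
an alpha/beta gain mechanically depresses relative theta, most strongly
in controls whose alpha dominates; at 1.15 the alpha/beta increase is
clearly detectable over 40 trials while the induced control theta shift
stays mostly below the per-subject significance threshold, matching the
qualitative pattern the analysis expects (patients, not controls, show
theta suppression).

Covariate coupling uses a Gaussian copula: each patient covariate is a
monotone (location-scale, for counts rounded) transform of a standard
normal correlated with the *negated* suppression latent by
2·sin(π·ρ_S/6), so the Spearman correlation between the covariate and
the theta contrast (which decreases in d) equals the target ρ_S in
expectation.  Defaults: total gray volume, right putamen, right insula
+0.85; surface holes −0.85; GOSe −0.70 (a stronger theta decrease goes
with better outcome).  Targets beyond |0.99| are rejected as
unreachable.  Cortical thickness is drawn from group-specific normal
distributions matching the study groups' tabulated means and SDs;
volume and surface-hole location/scale parameters are realistic values
chosen once (they are not tabulated in the source study).  GOSe and GCS
are quantile-mapped onto the empirical score multisets of the ten
observed patients, which confines GOSe to {3,…,7} and GCS to [5, 7];
controls receive GOSe 8, GCS 15.

What the generator does **not** emulate: volume conduction and
inter-electrode correlation (channels are independent), artifacts (eye
blinks, ECG, electrode drift), non-stationarity within epochs, any
spatial topography of the effects (every electrode carries the same
expected contrast), and the coupling between the beta-band stimulation
response and somatosensory cortical thickness — the pipeline runs that
battery (beta contrast vs paracentral/precentral thickness), but the
generator leaves those covariates uncoupled, so any significant cluster
there is by construction a false positive and serves as an in-band
calibration check.  Passing tests therefore show that the *statistics*
behave as designed — calibration, error control, sign recovery — not that
the pipeline is robust to real-world EEG artifacts or that spatial
cluster locations are meaningful beyond the adjacency structure.

## Numerical and design choices

* Epochs are half-open sample windows [onset, onset+L) at 0-based
  indices, onsets rounded to the nearest sample; partial trailing
  segments are dropped.  Rest fragments default to contiguous-from-start
  when capped; an evenly-spaced "sampled" mode exists.
* Artifact rejection is not implemented (epochs are assumed clean); an
  optional absolute-amplitude threshold can drop epochs, off by default.
* EDF support is a minimal plain 16-bit EDF reader/writer with a fixed
  ±3276.7 µV physical range (0.1 µV resolution) and a tab-separated
  sidecar events file; the fixed range makes write→read→write an exact
  fixed point.  An independent EDF reader is used as a cross-check in the
  tests.  A text epoch-archive dialect stores already-epoched data.
* |ρ| = 1 maps to a signed capped t (1e6), flagged rather than infinite,
  so cluster masses stay finite.
* Degenerate inputs: all-equal ANOVA responses report F = 0, p = 1;
  zero-variance rank tests report p = 1 with a flag; zero total spectral
  power in [2, 20) Hz is an error.

## Problem sizes used in the checks

Monte-Carlo checks scale the per-subject epoch counts down while keeping
the study-scale subject counts and the full permutation count: the
family-wise error check runs 300 null cohorts of 10 patients with 2
trials per stimulus type and 6 rest fragments; the recovery check runs
50 cohorts of 10 patients with 5 trials and 20 rest fragments at
coupling 0.85.  The permutation-floor scenario uses 20 patients with the
full trial structure and coupling 0.95, because at n = 10 one of 500
random permutations occasionally nearly reproduces the covariate
ordering and the observed mass then no longer exceeds every permuted
mass.  All seeds are fixed in the code.

## Known limitations

* The ANOVA's weighted-means sums of squares are exact for the balanced
  within-subject design used here; heavily unbalanced between-group
  designs would warrant a regression formulation.
* The Gaussian-copula targets hold in expectation; at n = 10 the
  realized rank correlation of a single cohort scatters visibly around
  the target (the recovery tests quantify this).
* Relative-power normalization couples bands: any absolute change in one
  band moves the relative power of all others.  Both normalization modes
  are first-class so sensitivity can be checked.
* The epoch-archive dialect stores values at 9 significant digits;
  round trips are exact only after the first write.
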
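# comareact

EEG reactivity to tactile stimulation as a marker of brain integrity and
outcome in post-traumatic coma — a tested, reusable replica of the full
analysis pipeline, exercised end to end on synthetic cohorts with
controlled statistical structure.

## The problem

After severe traumatic brain injury, whether a comatose patient's brain
still responds to touch carries prognostic information.  The analysis
implemented here works with 19-channel 10-20 EEG at 250 Hz recorded at
rest and during four tactile stimulus types (soft/hard brush × slow/fast
stroking; 10 trials of 10 s each), plus FreeSurfer-style morphometry
tables and clinical scores (GCS, GOSe).  Its core quantities:

* **Relative band power.**  Welch PSD per epoch and electrode,
  normalized to relative power over [2, 20) Hz and integrated over
  unit-width bins [2,3), …, [19,20); bands: slow 2–6, theta 4–6, alpha
  11–13 (8–12 for resting comparisons), beta 17–20 (16–20) Hz.
* **Group statistics.**  Mann–Whitney U for morphometry; mixed
  repeated-measures ANOVA, 2 GROUP × 5 CONDITIONS, on electrode-averaged
  power, with Bonferroni post-hocs.
* **Individual reactivity.**  Per subject and electrode, a rank test of
  40 stimulation trials vs 40 rest fragments at the Bonferroni-corrected
  threshold 0.05/19 ≈ 0.0026.
* **Cluster-based permutation correlation** (the core).  Per electrode,
  Spearman's ρ between the patients' band-power contrast Δ =
  stimulation − rest and a covariate (gray-matter volume, right
  putamen/insula volume, surface-hole count, GOSe, cortical thickness),
  converted to t = ρ√((n−2)/(1−ρ²)), thresholded at the 2.5th/97.5th
  permutation quantiles, clustered over the montage adjacency graph, and
  scored by cluster mass Σt against the maximum-mass null distribution
  from 500 covariate permutations; p = (b+1)/(N+1), Bonferroni across
  covariates.

Because no patient data are distributable, `comareact.synthetic_cohort`
generates a study-scale cohort (10 patients, 15 controls) whose EEG,
morphometry and outcomes carry the coupling structure the analysis is
designed to detect — see `docs/methods.md`.

## Worked example

```
python analysis/01_simulate_cohort.py    # EEG to scratch/, tables to scratch/cohort
python analysis/02_run_study_analysis.py # results to results/analysis
python analysis/03_null_calibration.py   # false-positive calibration table
```

Output of `02_run_study_analysis.py` on the default cohort (seed 2020):

```
median resting relative power (patient vs control):
   slow: 0.159 vs 0.100
  theta: 0.137 vs 0.080
  alpha: 0.029 vs 0.062
   beta: 0.018 vs 0.028
theta-decrease responders (patient): 10/10
theta-decrease responders (control): 5/15
significant clusters: 4
  [theta] right_putamen: sign +1, mass 104.8, p=0.002 (19 electrodes)
  [theta] surface_holes: sign -1, mass -105.4, p=0.002 (19 electrodes)
  [theta] gose: sign -1, mass -89.7, p=0.002 (19 electrodes)
  [beta] paracentral_thickness: sign -1, mass -11.7, p=0.020 (4 electrodes)
```

Reading this: synthetic patients show the expected resting profile
(elevated slow/theta, reduced alpha/beta relative power).  Every patient,
and a third of controls, shows a significant per-subject theta decrease
under stimulation.  The permutation battery recovers the generator's
couplings: the theta contrast correlates positively with right-putamen
volume and negatively with the damage proxy (surface holes) and — in the
direction that matters clinically — negatively with GOSe, i.e. stronger
theta suppression goes with better outcome; these clusters sit at the
p-floor 0.002 of the 500-permutation null.  The beta/paracentral cluster
is a battery-level false positive (that covariate is uncoupled in the
generator), the kind of event the calibration script quantifies.

The same pipeline runs from the shell:

```
comareact all --seed 7 --out /tmp/study          # simulate + analyze + report
comareact analyze --cohort <dir> --out <dir> --band-scheme resting
```

## Layout

```
src/comareact/      library: io_formats, synthetic_cohort, spectral,
                    group_stats, individual_stats, cluster_perm,
                    montage, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property, and study-level checks)
docs/methods.md     model, parameters, design choices, limitations
```
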
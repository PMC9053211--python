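# evmced

Development pipeline for a blood-based multi-cancer early-detection
(MCED) classifier built from extracellular-vesicle (EV) protein
measurements.

## The problem

A case-control screening study measures a panel of EV-associated
protein concentrations (plus age) in plasma from controls and from
patients with early-stage (I–II) pancreatic, ovarian and bladder
cancer, and asks: can a small marker panel plus a logistic model call
cancer at near-perfect specificity while keeping sensitivity useful for
screening?  Immunoassay data of this kind is awkward in three specific
ways — values fall below per-marker limits of detection (LOD),
concentrations span orders of magnitude, and the cohort is small enough
that a single train/test split is untrustworthy.  This package
implements the full classifier-development procedure for that setting:

1. **Preprocessing** — markers with ≥ 50% of values missing or below
   the LOD are excluded; remaining censored cells are imputed to the
   LOD; everything is log2-transformed; age enters untransformed.
2. **Marker selection** — recursive feature elimination (RFE) inside
   repeated stratified 5-fold cross-validation (100 repetitions).
   Within each training fold a full logistic model is fitted, the
   weakest marker by |β<sub>j</sub> · sd<sub>j</sub>| is removed, and the model is
   refitted down to one marker.  Each panel size is scored on the
   held-out fold by the **partial AUC** over the specificity band
   [0.75, 1.00] (raw trapezoidal area, maximum 0.25), emphasising the
   low-false-positive regime; the size maximising mean held-out pAUC
   wins, and the panel is assembled from the elimination-order ranks.
3. **Resampled evaluation** — 100 independent train/test splits (2/3
   vs 1/3, stratified by cancer type, so 184 controls always yield 61
   test controls), a fresh unpenalized logistic fit per split, a
   per-split threshold calibrated at > 99% specificity on the 61 test
   controls (score > threshold ⇒ positive; with 61 controls this means
   calling 61/61 correctly), per-subject **averaged held-out scores**,
   and a final call at the **averaged threshold** τ̄.
4. **Uncertainty** — Wilson two-sided intervals for every sensitivity
   and specificity; bias-corrected (BC, no acceleration) stratified
   bootstrap (B = 2000) intervals for the AUC of the mean scores;
   marker importance as the mean |β<sub>j</sub> · sd<sub>j</sub>| across the 100 fits,
   rescaled to max 100.

A synthetic-cohort generator (`evmced.simulate`) draws cohorts with the
same structure — log2-normal markers with block correlation, per-cancer
shifts on overlapping informative subsets, per-marker LODs, missing
values, and an age covariate — so the entire pipeline is testable
without any measurement data.

## Worked example

The numbered scripts under `analysis/` run the full procedure on the
study-shaped synthetic cohort (323 subjects, 42 markers) and write all
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_select_markers.py
python analysis/04_resample_evaluate.py
```

Output of the last step (abridged):

```
100 resamples of 34 markers + age; average threshold 1.0000
AUC of per-subject mean scores: 0.964 (95% BC bootstrap 0.946-0.980)
        category  n_subjects      metric   k estimate_pct ci_lower_pct ci_upper_pct
        Controls         184 specificity 183         99.5         97.0         99.9
All cancer cases         139 sensitivity  67         48.2         40.1         56.4
         Stage I          88 sensitivity  48         54.5         44.2         64.5
        Stage II          51 sensitivity  19         37.3         25.3         51.0
...
```

Reading this: of 184 controls, 183 fall at or below the averaged
threshold (specificity 99.5%, Wilson 95% CI 97.0–99.9), 67 of the 139
cases exceed it, and the per-subject mean held-out scores separate
cases from controls with AUC 0.964.  Per-cancer rows follow the
generator's planted effect ordering (pancreatic strongest, bladder
weakest).  The same pipeline runs end-to-end through one call
(`evmced run --simulate --outdir out/`) or stage by stage via the
`simulate`, `preprocess`, `select`, `evaluate` and `report`
subcommands; real measurement tables can be substituted for the
synthetic ones via `--measurements/--subjects/--markers`.

## Layout

```
src/evmced/         library: data model, io, simulate, preprocess,
                    roc, logistic, rfe, resample, pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md     models, assumptions, numerical choices
```
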
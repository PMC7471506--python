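# serostab

Serum-protein severity modeling for young, steroid-naïve Duchenne muscular
dystrophy (DMD) cohorts: weighted correlation-network clustering of an
aptamer proteomics panel, module–trait screening, repeated-cross-validation
elastic-net stability selection, sparse linear models of motor outcomes,
and cross-tissue validation against muscle-biopsy mRNA.

## Who this is for

DMD shows large patient-to-patient variability in motor function even
though every patient shares the same biochemical lesion. For a cohort of
~39 boys (4 to <7 years) with ~1305 serum proteins and four repeated
measurements of five motor outcomes, `serostab` answers: *which sets of
serum proteins, taken together, model a child's clinical severity at
baseline?* It is a library for statisticians and computational biologists
working with small-n / large-p biomarker panels; everything is importable
from Python, with a thin `serostab` CLI for batch runs.

## The method

With p ≫ n, single-protein testing is underpowered and unstable, so the
pipeline reduces dimension in stages:

1. **Network clustering (unsupervised).** Biweight midcorrelations between
   log2 protein profiles, raised to a soft-threshold power β chosen by the
   scale-free topology criterion, give adjacency a_ij = |bicor_ij|^β. The
   topological overlap measure TOM_ij = (Σ_u a_iu·a_uj + a_ij) /
   (min(k_i,k_j)+1−a_ij) feeds average-linkage clustering into modules;
   each module is summarized by its eigenprotein (ME, the first principal
   component of its standardized members).
2. **Screening.** Pearson r of each ME with each outcome (two-sided t,
   n−2 df); modules with p < 0.15 are retained (liberal by design; no
   multiplicity correction at a filtering step). Members need module
   membership |kME| ≥ c and standardized intramodular connectivity
   k̂ ≥ c (c = 0.70 / 0.63 for the strength / endurance traits).
3. **Stability selection.** Elastic net (α = 0.95, penalty by 10-fold
   CV-minimum error) repeated over 100 fresh fold splits; proteins
   selected ≥ 60/100 times form the panel, confirmed by a final LASSO.
4. **Validation.** R² (squared Pearson) of predictions against the
   four-visit mean and against each single visit; ridge transfer of the
   strength panel to the other timed tests with coefficient sign
   concordance; and biopsy mRNA cross-validation — strict `_at` probe
   mapping, moderated (empirical-Bayes) normal-vs-DMD t-tests, Spearman
   correlation with histopathology grade oriented "toward mild", with
   joint Benjamini–Hochberg FDR across trait panels.

Because the underlying clinical-trial serum matrix is not public, the
package ships a first-class synthetic-data generator
(`serostab.synthetic`) that plants latent-factor modules, causal proteins,
visit-level noise at realistic %CV, and biopsy effects — with the ground
truth returned for recovery testing. See `docs/methods.md` for the full
model and every numerical choice.

## Worked example

```bash
python examples/02_network_modules.py
```

prints (scaled-down cohort: 80 subjects × 300 proteins, 5 planted modules):

```
soft-threshold power beta = 7 (smallest power with signed scale-free fit R^2 >= 0.8)
detected module sizes: {'M01': 80, 'M02': 60, 'M03': 51, 'M04': 42, 'M05': 30}
unassigned (grey): 37
adjusted Rand index vs planted partition: 0.982 (1.0 = perfect recovery)
median |kME| of assigned proteins to their own module: 0.73 — hub proteins approach 1.
```

Every planted module is recovered essentially intact (ARI ≈ 1): the pipeline's
clustering stage finds exactly the co-expression structure the generator
planted, and the pure-noise proteins land in "grey". The other examples
walk the remaining capabilities: `01_simulate_cohort.py` (repeated-measure
%CV table), `03_screen_and_select.py` (screening through the final LASSO),
`04_biopsy_validation.py` (fold changes and severity correlations with
their sign conventions), `05_full_pipeline.py` (end-to-end run with a
reproducibility manifest).

The same pipeline from the shell:

```bash
serostab run-all --seed 7 --out results/run7
```

## Layout

```
src/serostab/     synthetic, preprocess, network, screen, selection,
                  biopsy, pipeline, io, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, acceptance)
docs/methods.md   model, parameters, numerical choices, limitations
```
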
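# glioconnect

Glioblastoma cells connect into networks through tumor microtubes (TMs) and
gap junctions, and the highly connected cells drive invasion and therapy
resistance.  `glioconnect` reimplements, as a tested Python pipeline, the
computational core of deriving a **tumor-cell connectivity signature** from
sorted (sc)RNA-seq and validating it functionally:

* **Signature derivation** — per-line Wilcoxon rank-sum marker tests between
  sorted high/low-connectivity groups, aggregated by a three-line consistency
  rule (same direction in all three lines, or same direction with
  |log FC| ≥ 0.4 in two); a bulk route via a negative-binomial Wald test with
  a cell-line covariate (adjusted p < 0.05, |log2 FC| ≥ 1); and a
  labeling-intensity cascade of five ordered filters with diffusion
  correction against a constitutively labeling control.
* **Connectivity signature score** — per cell, the module score of the
  upregulated gene set minus that of the downregulated set, where a module
  score is mean expression of the set minus the mean of expression-bin-matched
  control genes (24 bins, 100 controls per gene).  A cell is predicted highly
  connected when its up-score exceeds its down-score; predictions are
  evaluated against the sorted labels with confusion metrics, against
  random-gene-set chance controls, and stratified into score quartiles.
* **Cell-state annotation** — module scores for the malignant states
  AC/MES1/MES2/OPC/NPC1/NPC2 (+cycling), argmax assignment, the 2D butterfly
  projection `Y = max(S_AC,S_MES1,S_MES2) − max(S_OPC,S_NPC1,S_NPC2)` with the
  branch-dependent X axis, and the cluster-level malignant/non-malignant
  typing rule (NMS = S_type − S_malignant thresholded at median + MAD).
* **Calcium coactivity** — Gaussian smoothing (σ = 10 s) and peak detection
  on fluorescence traces (frame interval 1.52 s); for each active cell pair
  (≥ 4 peaks, ≤ 100 µm apart) the best lagged Pearson correlation
  `rho(a,b) = max_τ corr(a_{i−τ}, b_i)` over 10-min segments, with lags
  restricted to propagation speeds of 4–25 µm/s (max shift 25 s); a
  linear-shift null (partner trace displaced by ΔT > 5 min) calibrates the
  coactivity threshold at its 95th percentile.
* **Weighted histoscore** — immunohistochemistry quantification
  `score = Σ_r r · P_r` over staining ratings r ∈ {0..3}, range 0–300.

The study's raw data are controlled-access, so a first-class synthetic-data
module generates every input with planted ground truth: negative-binomial
counts with planted up/down connectivity genes across 3 lines × 2 sorted
groups, discrete cell states, bulk counts with a line covariate, calcium
recordings in which transients propagate between connected cells with
lag = distance/speed, and per-cell staining ratings.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_derive_signature.py
python analysis/03_score_and_classify.py --seed 1
python analysis/04_calcium_coactivity.py --seed 1
python analysis/05_histoscore.py --seed 1
```

With seed 1 this prints:

```
simulated 1800 cells x 800 genes (40 up / 31 down planted)
derived 39 up / 31 down connectivity genes; 70/71 planted recovered (hypergeometric p = 1.16e-100)
accuracy 1.000 (sens 1.000, spec 1.000); random-set control accuracy 0.504
threshold 0.301 (95th pct of 210 null correlations); 41 coactive edges, recall 0.98, precision 1.00
        all_high: histoscore  300.00 (population value 300)
    all_negative: histoscore    0.00 (population value 0)
```

Reading: the derivation cascade recovers 70 of the 71 planted connectivity
genes; classifying cells by their connectivity score separates the sorted
groups perfectly at effect size 3, while 100 random signatures of the same
size sit at chance (0.504); the coactivity threshold calibrated on the
linear-shift null recovers 98 % of the planted cell-to-cell connections with
no false edges; and the histoscore extremes take their analytic values 300
and 0.

The same machinery is available as a CLI
(`glioconnect simulate|score|evaluate|coactivity|histoscore`) for use on
external matrices, signature TSVs and trace/position CSVs.

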
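# dfcpipe

Classification of patients vs controls from **dynamic functional
connectivity (DFC)** of resting-state ROI time series, with a synthetic
cohort generator that plants recoverable, time-localized connectivity
effects so every stage of the pipeline can be validated against ground
truth.

The scientific question: major depressive disorder alters inter-regional
brain connectivity, but some of those alterations are *transient* — present
only during sub-intervals of a scan.  A static (whole-series) correlation
matrix dilutes such effects; sliding-window correlation resolves them.
This package implements the full discrimination pipeline on top of that
idea and quantifies, on synthetic cohorts, when and by how much dynamic
features outperform static ones.

## Pipeline

For subject *s* with ROI series X ∈ ℝ^{T×N} and window scheme (width *w*,
step *h*), window *k* covers [kh, kh+w) and yields the Pearson matrix
R⁽ᵏ⁾ ∈ [−1,1]^{N×N}; with T = 200, w = 50, h = 2 there are W = 76 windows
(w is chosen as 1/f_min = 100 s at TR = 2 s).  Upper-triangle entries of
all windows are flattened window-major into W·N(N−1)/2 features per subject
(76 × 37,128 = 2,821,728 at N = 273).  Then:

1. **Covariate adjustment** — each feature is replaced by its residual on
   intercept + gender + education (least squares across subjects).
2. **Screening** — two-sample pooled-variance t-test per feature; keep
   p < 0.001 (uncorrected).
3. **Nonlinear SVM-RFE** — train an RBF-kernel SVM and score every
   surviving feature f by the kernel-space margin sensitivity
   ΔJ(f) = ½ aᵀK a − ½ aᵀK₍₋f₎ a, with a the label-weighted dual
   coefficients on the support vectors and K₍₋f₎ the kernel recomputed
   without feature f (for RBF, K₍₋f₎ = K ⊙ exp(γ d_f²)); iteratively
   eliminate the lowest-ΔJ features.
4. **Subset selection** — cross-validated ROC AUC of every top-*n* subset;
   the argmax (ties → smallest *n*) is the optimal subset, reported with
   rank weights rescaled linearly onto [1.00, 0.00].
5. **Evaluation** — repeated stratified 10-fold CV, LOOCV, and a
   73/26 hold-out protocol in which all selection happens on the training
   split only; sensitivity is computed on patients (+1), specificity on
   controls (−1), AUC from SVM decision values.
6. **Characterization** — selected columns decode back to
   (window, region i, region j), join an atlas label table
   (region/network names), yield node degrees, and correlate with clinical
   severity scores (HAMD/HAMA) in patients after covariate adjustment.

The synthetic generator produces piecewise-stationary Gaussian ROI series,
band-limited to 0.01–0.1 Hz, in which designated edges carry a correlation
delta only during designated time epochs for patients — so ground truth is
known at the level of (window, edge) features.  See `docs/methods.md` for
the model, its assumptions, and what it does not emulate.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_screen_features.py
python analysis/04_select_features.py
python analysis/05_evaluate_models.py
python analysis/06_characterize_selection.py
```

simulates a 43-patient / 56-control cohort (N = 30 regions, three planted
transient edges, |Δr| = 0.5 over 70-timepoint epochs), extracts
99 × 33,060 DFC and 99 × 435 SFC features, and prints, among other things:

```
retained 116 of 33060 features at p<0.001; 104 lie on planted edges
optimal subset: 31 of 116 screened features (peak selection-CV AUC 0.9527)
DFC - SFC AUC gap: +0.1010 (dynamic features win)
```

with the repeated-CV table (percent; AUC as a fraction):

| features | optimal n | sensitivity | specificity | accuracy | AUC |
|---|---|---|---|---|---|
| DFC | 31 | 88.8 | 90.9 | 90.0 | 0.952 |
| SFC | 24 | 0.0 | 100.0 | 56.6 | 0.851 |

Screening is near-perfectly enriched for the planted edges, the selected
subset recovers all three planted effects, and the dynamic features beat
the static ones by ~0.10 AUC — the static SVM even collapses to
majority-class prediction under the 43/56 imbalance while its decision
values still rank reasonably (AUC 0.85), which is exactly why AUC, not
accuracy, drives subset selection.  The final step maps the 31 selected
connections onto 10 regions, 7 networks and 30 distinct windows and finds
the planted negative HAMD coupling (strongest: r = −0.49, p = 0.0009).

The same machinery is scriptable via the `dfcpipe` CLI
(`simulate`, `extract`, `screen`, `select`, `evaluate`, `characterize`,
`run-all`) or the `dfcpipe.pipeline.run_all` API, which writes per-stage
artifacts plus a manifest of content hashes for reproducibility.

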
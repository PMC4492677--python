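# tfcoherence

Regulon-constrained Bayesian inference of transcription-factor (TF)
activities from time-course expression data, with *coherence-plot*
comparison of TF behaviour between two experimental conditions.

## The problem

Genome-wide expression time courses — for example an anaerobic *E. coli*
culture sampled at 10, 20, 40, 60 and 120 min after adding a CO-releasing
compound versus its CO-depleted control — report thousands of transcript
changes but say nothing directly about the regulators driving them.  A TF's
*activity* (its effective regulatory output over time) is not measured by
its own transcript level; it must be inferred from the coordinated
behaviour of its regulon, the set of genes it controls.  This package is
for systems biologists who have (i) per-gene log-ratio expression matrices
for two conditions and (ii) a TF→gene regulon map (RegulonDB/EcoCyc-style
edge list), and who want per-TF activity profiles with uncertainties and a
principled, uncertainty-aware comparison of each TF between the conditions.

## The model

Expression of gene *n* at time *t* is modelled bilinearly,

```
y[n,t] = mu[n] + sum_m X[n,m] * b[n,m] * c[m,t] + eps[n,t],
eps ~ N(0, sigma^2)
```

where `X` is the fixed binary connectivity, `b[n,m]` the gene-specific
regulatory strength (free-signed: activation or repression is learned),
`c[m,t]` the latent activity of TF *m*, and `mu[n]` a gene baseline.
Priors are Gaussian on `b` and `mu`, and a Gaussian random walk over the
actual minute grid on each activity profile `c[m,·]`.  The posterior is
approximated by mean-field variational Bayes (`q(b,mu) * q(c)`, closed-form
point update for `sigma`), iterated to convergence of the evidence lower
bound, which is guaranteed non-decreasing.  The bilinear form is
unidentifiable per TF up to sign/scale, so a deterministic gauge is fixed:
unit-norm strength vectors with a positive largest-magnitude entry.

Two fitted conditions are compared per TF on the coherence plot:

* **x**, profile difference = `1 − |Pearson r|` between the two
  posterior-mean profiles (kinetic similarity, scale- and sign-free);
* **y**, magnitude difference = `| ‖c_A‖₂ − ‖c_B‖₂ |` (amplitude).

Posterior uncertainty is propagated by Monte-Carlo draws from the marginal
posteriors, giving the mean ± SD of `|r|` (the x error bar) and the SD of
the draw-wise magnitude difference (the y error bar).  TFs responding
identically in both conditions cluster at the origin (quadrant C); TFs
differing in both kinetics and amplitude land in the far corner (B).

The package also includes the accompanying expression-level computations —
inclusive ≥2-fold / ≤0.5-fold significance calls, per-category up/down
percentages, genome-fraction-altered summaries, natural-log heat values —
a synthetic-data generator with known ground truth (coherent vs divergent
TFs planted by construction), and closed-form bench-assay arithmetic
(Beer–Lambert cytochrome quantitation, CFU/ml, linear-growth doubling
times).

## Worked example

`examples/infer_activities.py` simulates a 300-gene study (16 TFs, 5 time
points, noise SD 0.1), fits condition A and checks recovery:

```
converged in 375 sweeps; fitted noise SD 0.1062 (true 0.1)
TF     |r(truth, estimate)|
BaeR   0.9999
CpxR   1.0000
...
median recovery |r| over 16 TFs: 1.0000
```

`|r|` is the absolute Pearson correlation between each planted activity
profile and its posterior-mean estimate — near 1 means the time course is
recovered up to the sign/scale gauge.  The fitted noise SD matching the
simulated value shows the variance decomposition is calibrated.

`examples/coherence_plot.py` then fits both conditions and compares them:

```
  tf  mean_abs_pearson  sd_abs_pearson  profile_difference  magnitude_difference quadrant
BaeR             1.000           0.000               0.000                 0.146        C
 ...
H-NS             0.685           0.007               0.315                 1.023        A
NarP             0.163           0.007               0.838                 2.998        B
```

The eight planted-coherent TFs (BaeR, CpxR, CRP, CysB, Fis, FNR, Fur, GadX)
show `|r| ≈ 1` and sit in quadrant C near the origin; the divergent eight
spread towards high profile and magnitude differences — the contrast the
method is designed to expose.  Other capabilities are demonstrated in
`examples/simulate_dataset.py`, `examples/fold_change_summaries.py` and
`examples/bench_calculations.py`, and the same stages are available from a
shell via the `tfcoherence` CLI (`simulate`, `infer`, `coherence`,
`summarize`, `assay`, `run`).

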
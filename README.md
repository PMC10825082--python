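# bjtvd — total-variation denoising for break-junction conductance traces

Single-molecule break-junction (BJ) experiments repeatedly pull apart an
atomic metal contact and record conductance versus electrode displacement.
When a molecule bridges the freshly formed nanogap, the trace shows a
*plateau* at a characteristic conductance, and molecules with several
junction configurations show several plateau levels.  Individual traces are
too noisy to read these states off directly, and the usual remedy — pooling
thousands of traces into conductance histograms — averages away exactly the
per-trace information one wants.

`bjtvd` implements a per-trace analysis built on **total-variation
denoising (TVD)**.  A raw log-conductance series G_raw is replaced by the
reconstruction G_rec minimizing

    (1/2) Σₙ (G_raw,n − G_rec,n)² + λ Σₙ |G_rec,n+1 − G_rec,n|

whose solution is piecewise constant: noise is suppressed while genuine
conductance steps survive.  The nondifferentiable objective is minimized
with ADMM (tridiagonal x-update, soft-threshold z-update), with a direct
exact 1-D TV solver as an independent cross-check.  On top of the denoiser
the package provides:

* a **simulator** for three validation trace classes (two-state, high-only,
  low-only) with a metal-contact mixture region and region-dependent
  Gaussian noise;
* **plateau analysis**: segmentation of the reconstruction, clustering
  under the identical-state bound log(2) ≈ 0.3, molecular-window filtering,
  nearest-state assignment, and per-state detection statistics;
* **1-D and 2-D conductance histograms** (conductance × stretch length,
  traces aligned at metal rupture);
* **supervised trace classification** from per-trace conductance-histogram
  features, comparing raw versus TVD-preprocessed inputs (random forest;
  F-measure = harmonic mean of sensitivity and specificity).

The denoiser, featurizer and classifier are scikit-learn-style estimators
(`TotalVariationDenoiser`, `MovingAverageSmoother`,
`TraceHistogramFeaturizer`, `HistogramTraceClassifier`) and compose with
sklearn pipelines; module-level functions (`tvd_admm`, `tvd_exact`,
`detect_plateaus`, `train_and_evaluate`, ...) wrap them for scripting.

## Worked example

```python
from bjtvd import (TVDConfig, generate_trace, tvd_admm, detect_plateaus)

trace = generate_trace(1, rng_seed=42)          # noisy two-state trace
result = tvd_admm(trace.log_g, TVDConfig(lam=1.0))
print(f"converged in {result.n_iter} iterations")
for p in detect_plateaus(trace.with_reconstructed(result.reconstructed)):
    print(f"{p.assigned_state:>4}: level {p.level:+.2f}, "
          f"length {p.length_nm:.2f} nm")
```

prints

```
converged in 1851 iterations
high: level -2.52, length 0.60 nm
 low: level -2.96, length 0.42 nm
```

i.e. the denoised trace resolves the high- and low-conductance states (true
levels −2.5 and −3.0, drawn per trace with sd 0.1) and their ~0.5 nm
extents from a single noisy trace.

The same flow runs from the shell:

```bash
bjtvd simulate --n-per-class 1000 --seed 1 --out traces.tsv
bjtvd denoise  --in traces.tsv --lambda 1.0 --out reconstructed.tsv
bjtvd plateaus --in traces.tsv --out plateaus.tsv
bjtvd hist     --in traces.tsv --denoised --out hist.tsv
bjtvd classify --in traces.tsv --preprocess tvd --report report.json
bjtvd run-all  --seed 1 --n-per-class 1000 --out-dir out/
```

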
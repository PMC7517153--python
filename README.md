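# dyncorr

Estimation of **dynamic bivariate correlation** — the correlation between two
time series that itself changes over time — with uncertainty quantification
and hypothesis tests. The problem is central to dynamic functional
connectivity in neuroscience: pairs of fMRI region time courses or local
field potential (LFP) recordings whose coupling waxes and wanes, often in
the presence of extreme values (movement artifacts, heavy-tailed noise).

Three estimators are provided, as scikit-learn-style estimator classes over
a `(T, 2)` array of paired observations:

- **Sliding window (SW)** — `SlidingWindowCorrelation(ws)`: the Pearson
  correlation within a moving window of `ws` consecutive samples,
  ρ̂<sub>t</sub> = corr(y₁, y₂ on [t−ws+1, t]), defined for t = ws..T.
  Simple, but noisy and badly fooled by outliers.
- **DCC-GARCH** — `DCCCorrelation()`: the econometric dynamic conditional
  correlation model, fitted by two-step quasi-maximum likelihood. Step 1
  fits GARCH(1,1) volatilities σ²<sub>i,t</sub> = ω<sub>i</sub> +
  α<sub>i</sub> y²<sub>i,t−1</sub> + β<sub>i</sub> σ²<sub>i,t−1</sub>
  per series and standardizes ("DE-GARCHing", r<sub>t</sub> =
  D<sub>t</sub>⁻¹ y<sub>t</sub>); step 2 runs the targeted quasi-correlation
  recursion Q<sub>t</sub> = (1−a−b)Ŝ + a r<sub>t−1</sub>r′<sub>t−1</sub> +
  b Q<sub>t−1</sub> and rescales R<sub>t</sub> =
  diag(Q<sub>t</sub>)<sup>−1/2</sup> Q<sub>t</sub>
  diag(Q<sub>t</sub>)<sup>−1/2</sup>. Excellent for well-behaved Gaussian
  data; numerically fragile under heavy tails (the fit reports its guard
  activations in a diagnostics record).
- **Weighted graph algorithm (WGA)** — `WeightedGraphCorrelation(ws)`: each
  series becomes a fully connected graph on its T time points with arctan
  chord-slope edge weights w<sub>ab</sub> = arctan((x(t<sub>b</sub>) −
  x(t<sub>a</sub>)) / (t<sub>b</sub> − t<sub>a</sub>)); the estimate at time
  i is the Pearson correlation between the two series' element-wise-median
  weight profiles over the last `ws` weight vectors. The arctan caps the
  influence of extreme values — this is the robust estimator of the three.

Around the estimators: synthetic scenario generators with known
time-varying correlation (`dyncorr.simulate`), multivariate linear process
bootstrap (MLPB) confidence bands and pointwise significance
(`dyncorr.uncertainty`), tests of "is the correlation actually dynamic?"
via the κ²_med and excursion (S) statistics (`dyncorr.hypotests`), and a
replicated experiment runner (`dyncorr.experiments`).

## Worked example

Draw a pair whose true correlation follows a slow sinusoid
(p(t) = sin(t/64), design `D2b`), estimate it, and test for dynamics:

```bash
$ dyncorr simulate --design D2b --T 600 --seed 7 --out pair.csv --truth truth.csv
wrote 600-point normal pair under D2b to pair.csv
$ dyncorr estimate --method wga --ws 15 --in pair.csv --out path.csv
wrote wga path over t=15..600 to path.csv
$ dyncorr test --statistic kappa_med --boot 200 --seed 1 --in pair.csv --out result.json
kappa_med = 0.4012, 95% CI (0.398, 0.5087): dynamic (reject static null)
```

The statistic κ²_med = 0.40 is the variance of the estimated correlation
path around its median; its bootstrap 95% interval excludes zero, so the
static-correlation null is rejected — correct, since the generating
correlation really does oscillate. Scoring the same run in Python:

```python
from dyncorr import read_series, read_path, wga_correlation, sw_correlation, mse

pair, truth = read_series("pair.csv"), read_path("truth.csv")
print(mse(wga_correlation(pair), truth))   # 0.0303
print(mse(sw_correlation(pair), truth))    # 0.0340
```

The WGA path tracks the moving truth more closely than the 15-point sliding
window; the gap widens dramatically under heavy-tailed (Cauchy) noise.

Confidence bands for the path come from `dyncorr ci` (blockwise MLPB
bootstrap, or the closed-form Fisher z-transform band with
`--ztransform`), and `dyncorr experiment` reproduces whole replicated
simulation studies with mean(SD) summary tables and a reproducibility
manifest.

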
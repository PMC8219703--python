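# hyporeact

Reactive-transport analysis of micropollutant transformation along hyporheic
flowpaths in river-simulating flumes.

Streambeds exchange water with the stream through bedform-induced "pumping";
on the way through the sediment, pharmaceuticals and other organic
micropollutants are degraded and retarded.  `hyporeact` is for researchers
who have porewater breakthrough curves from samplers positioned along such
flowpaths and want compound- and flowpath-specific removal rates and
half-lives.  It provides:

- a 1-D advection–dispersion–retardation–decay solver,
  `R ∂c/∂t = D ∂²c/∂x² − v ∂c/∂x − k c`, driven by a time-varying
  surface-water boundary;
- DREAM-style multi-chain Bayesian inference of `(k, R, v, L, D)` per
  compound and flowpath, with a two-stage scheme that calibrates the
  dispersion prior on a conservative reference compound
  (hydrochlorothiazide) and chains it into every other fit;
- post-processing to half-lives `DT50 = ln 2 / k` with per-flowpath
  detectability thresholds ("Inf" masking), interquartile ranges and RMSE;
- a synthetic flume-experiment generator (known ground truth, lognormal
  measurement noise, LOQ censoring with `LOQ/√2` substitution) so the whole
  pipeline is testable end to end without external data;
- a CLI: `hyporeact simulate | fit | report | recover`.

See `docs/methods.md` for the model, priors, sampler and their assumptions.

## Worked example

Simulate a benchmark flume dataset on flowpath d, fit it, and render the
results table:

```bash
hyporeact simulate --seed 1 --flowpaths d \
    --compounds hydrochlorothiazide,metformin --out data.csv
hyporeact fit --data data.csv --out-dir results --seed 1 \
    --chains 20 --generations 2500 --allow-nonconverged
hyporeact report --results results/results.csv
```

which prints (medians with IQRs in brackets; empty columns are flowpaths
not present in the dataset):

```
           compound R_a R_b R_c         R_d DT50_a DT50_b DT50_c      DT50_d  RMSE_average
hydrochlorothiazide             1.85 (3.92)                              Inf         1.430
          metformin             9.07 (3.61)                      29.5 (11.9)         0.183
```

Reading it: the conservative reference compound (true k = 0) shows no
measurable removal — its median half-life exceeds the flowpath's
detectability threshold, hence `Inf` — while the metformin-like compound
combines strong retardation (median 9.07 against a true value of 8) with a
29.5 h half-life (truth 34.7 h).  The wide IQRs are real: a single
breakthrough curve constrains `k`, `R`, `v` and `D` only jointly (see the
identifiability discussion in `docs/methods.md`), which is also why the
fit prints Gelman–Rubin warnings that `--allow-nonconverged` downgrades.
`results/posterior_samples.csv` holds the tidy pooled chains behind these
summaries.

The same workflow is available as a library, in scikit-learn style:

```python
from hyporeact import TransportCurveFitter, BoundarySeries, build_prior_set, flowpath_by_id
from hyporeact.priors import DEFAULT_DH_POSTERIORS

geom = flowpath_by_id("b")
fitter = TransportCurveFitter(
    priors=build_prior_set(geom, DEFAULT_DH_POSTERIORS["b"]),
    boundary=BoundarySeries.constant(11.5, 504.0),
    n_generations=2500, random_state=0,
)
fitter.fit(times_h, concentrations)      # runs the sampler
fitter.summary_.median["k"]              # posterior median removal rate, 1/h
fitter.predict(times_h)                  # forward curve at the posterior median
```

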
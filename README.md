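# pfclust

Statistical pipeline for asking whether sensory-activated **cerebellar
parallel fibres (PFs)** are clustered on the micron scale, from in vivo
two-photon calcium imaging of sparsely labelled axons.

The package is aimed at systems neuroscientists analysing population
imaging of axons: it takes fluorescence traces (time × ROI), 2-D fibre
coordinates within bounded imaging windows, and fibre × trial response
rasters, and runs the complete chain of inference:

1. **Event detection** (`pfclust.events`) — ΔF/F conversion, Fourier
   high-pass detrending, varying-baseline thresholding with the
   two-standard-deviations rule, per-event SNR, burst decomposition of
   1 kHz linescans, and bimodal latency fitting.
2. **Co-activation statistics** (`pfclust.coactivity`) — under
   independent activation the number of co-active fibres in a window of
   *n* labelled fibres is Binomial(*n*, *p*<sub>response</sub>); the
   observed per-window counts are tested against the pooled binomial
   expectation by χ² goodness of fit, and active-pair distances are
   compared with all-pair distances (Mann–Whitney, bootstrap CDF
   envelopes).
3. **Spatial randomness test** (`pfclust.spatial`) — the mean
   nearest-neighbour distance (NND) of a fibre map is compared with
   10,000 uniform patterns of equal size in the same region; shorter
   NND ⇒ clustering, longer ⇒ regular spacing, two-sided Monte Carlo
   p-value with the add-one convention.
4. **Trial-variability coupling** (`pfclust.coupling`) — each
   within-window fibre pair gets the Pearson correlation of its binary
   response rasters and its two-sided p-value (the "probability of
   independence"); pairs with p < 0.05 are classified as sharing a
   presynaptic driver.
5. **Labelling-density calibration** (`pfclust.density`) — bouton counts
   in 1 μm sections → labelled-fibre density → labelled fraction →
   expected labelled fibres per Purkinje cell, with a one-sample t-test
   plausibility check.
6. **Synthetic experiments** (`pfclust.synthetic`) — ground-truthed
   generators for every input: CSR / jittered-lattice / Thomas-cluster
   fibre maps, spike-to-fluorescence forward model, shared-driver
   population rasters, and bouton maps — so every stage above is
   validated against known truth without any external data.

## Worked example

```python
from pfclust import (ClusterParams, SimulationConfig,
                     csr_monte_carlo_test, simulate_point_pattern)

cfg = SimulationConfig(
    seed=42,
    pattern_kind="thomas_cluster",
    cluster_params=ClusterParams(n_parents=5, offspring_per_parent=3,
                                 sigma_um=3.0),
)
pattern, truth = simulate_point_pattern(cfg)
result = csr_monte_carlo_test(pattern, n_replicates=10_000, seed=1)
print(result.summary())
```

prints

```
CSR Monte Carlo test (n=15 points, 10000 replicates)
  observed mean NND :    3.675 um
  null mean [95% CI]:   13.491 [9.530, 17.420] um
  direction         : clustered
  two-sided p       : 0.0002
```

The 15 simulated fibre cross-sections sit in clusters of ~3 μm
dispersion inside a 56 × 150 μm window, so their mean nearest-neighbour
distance (3.7 μm) falls far below what uniform placement predicts
(13.5 μm): the map deviates from complete spatial randomness towards
clustering at p = 2 × 10⁻⁴ (the smallest value 10,000 replicates can
resolve two-sidedly).

The population-level test works the same way:

```python
from pfclust import (CouplingStructure, binomial_null, coactivity_test,
                     simulate_population_experiment)

cfg = SimulationConfig(seed=7, coupling_structure=CouplingStructure(
    group_size=3, reliability=0.8))
fovs = simulate_population_experiment(cfg, n_fovs=85, n_trials=40)
ns = [f.pattern.n_points for f in fovs]
observed = [int(f.truth.responder.sum()) for f in fovs]
print(coactivity_test(observed, binomial_null(ns, cfg.p_response)).summary())
```

```
co-activation χ² test: χ²=25.362, df=2, p=3.11e-06
```

Fibres recruited in groups of three by shared mossy-fibre drive produce
far more multi-fibre windows than the binomial null allows, and the χ²
test sees it. Finally, `expected_pf_count_per_pc(0.0038)` returns
`570` — the labelled-fibre count predicted for a Purkinje cell when
0.38% of its 150,000 crossing fibres carry indicator.

There is also a CLI (`pfclust simulate|detect|respond|coactivity|
csrtest|stitch|coupling|density|report`); every stochastic subcommand
takes `--seed` and is exactly reproducible.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic data
generator and its relation to real recordings, all default parameters,
and the package's numerical conventions.
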
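# Methods

This note documents the statistical machinery in `pfclust`: the models
and their assumptions, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## 1. The scientific setting

Cerebellar granule cells send parallel fibres (PFs) through the
molecular layer, where each Purkinje cell's planar dendritic tree
(~200 μm wide) is crossed by on the order of 150,000 of them. With
sparse bulk labelling (~0.4% of fibres carrying a calcium indicator), a
56 μm sagittal imaging window contains a handful (4–21, median ~13) of
resolvable fibres. The pipeline asks three questions about a sensory
stimulus delivered repeatedly to such windows:

* do more fibres respond *together* than independent activation
  predicts (co-activation),
* are responding fibres *closer in space* than chance (clustering),
* and does trial-to-trial variability reveal *common presynaptic
  drive* between pairs (coupling)?

## 2. Event detection (`events`)

**ΔF/F.** Raw traces are converted as (F − F₀)/F₀ with F₀ a rolling
20th percentile over 2 s — robust to transients riding on the baseline.
Any window with F₀ ≤ 0 is an error naming the offending time.

**Varying-baseline detection.** On ΔF/F the same rolling percentile
tracks slow drift. Because a 20th percentile sits a fixed quantile
offset below the noise mean, the residual is re-centred on its median
before thresholding. Noise σ is estimated as 1.4826 × MAD of the
residual. An event is an excursion above the detection threshold of
2σ (the two-standard-deviations rule) that

* holds the threshold for ≥3 consecutive frames (minimum duration), and
* once triggered, extends down to a 1σ floor (hysteresis), so noise
  flutter around the threshold during the decay cannot split one
  transient into several.

The duration rule bounds the false-positive rate on pure noise by the
Gaussian run probability Φ(−2)³ ≈ 1.2 × 10⁻⁵ per sample (≈0.02
spurious events per 60 s at 32 Hz), verified by simulation. A calcium
transient of amplitude A stays above 2σ for about τ·ln(A/2σ) — half a
second at the default τ = 0.4 s and SNR 7 — so real events are
unaffected. Onset is the first suprathreshold frame; amplitude is the
peak of the residual; per-event SNR is amplitude over the RMS of the
pre-event residual (0.5 s window, falling back to the whole-trace
sub-threshold RMS when the window is contaminated).

Design note: the detection scheme is this package's own construction —
it is validated against synthetic ground truth (≥95% sensitivity and
precision, onsets within one frame, at amplitude 0.5 ΔF/F over 0.07
noise), not against any third-party routine's event counts. For the
recovery benchmark the generator uses a *fixed* 0.5 ΔF/F amplitude:
that pins the benchmark at the intended SNR ≈ 7 operating point, while
a dispersed amplitude distribution would mix in genuinely sub-threshold
events and measure the amplitude distribution rather than the detector.

**Response classification.** A trial is a response when an event onset
falls in [stimulus, stimulus + 0.2 s); 0.2 s covers both latency peaks
(~10 and ~22 ms) with slack for 32 Hz framing. Overlapping response
windows (inter-stimulus interval < window) are an error. A fibre is a
*responder* when its stimulus-triggered average exceeds 2 s.d. of its
0.5 s pre-stimulus baseline within the window.

**Bursts and latencies.** Sensory-evoked transients ride on bursts of
2–3 action potentials at up to ~172 Hz; these are only resolvable in
1 kHz linescans (the 32 Hz framing regime raises an error). Steps are
derivative peaks above 5× the derivative noise within 100 ms after the
stimulus, with a 4 ms minimum spacing; the maximum intraburst frequency
is the reciprocal of the smallest inter-step interval, defined only for
≥2 steps. Latencies are histogrammed at 2 ms bins and fitted with a
two-component Gaussian mixture (EM, 10 restarts, fixed seed); the fit
is flagged "not bimodal" when the component means are within 3 pooled
s.d. of each other.

## 3. Co-activation null (`coactivity`)

With per-fibre response probability p and nᵢ labelled fibres in window
i, independent activation makes the co-active count kᵢ ~ Binomial(nᵢ, p).
The pooled expected histogram is the sum of the per-window pmfs. The χ²
statistic compares observed and expected histograms over k with the
high-k tail pooled until its expected count reaches 3; df = bins − 1.

*Why 3 and not Cochran's 5:* at p ≈ 0.03 and 85 windows the expected
tail beyond k = 1 is ≈4; pooling to 5 merges the entire k ≥ 2 tail into
the k = 1 bin and discards exactly the bins where clustering shows up
(power against a shared-driver alternative drops from ~1.0 to ~0.7).
With the threshold at 3 the test remains well calibrated (rejection
rate 0.049 at α = 0.05; KS test of the p-value distribution against
uniform, p ≈ 0.9 over 1,000 null experiments) while keeping the tail.
The threshold is exposed as `min_expected`.

The analysis pools one count per window across window sizes (stratified
testing is not attempted); p for the null is by default the responder
fraction of the same dataset, with an externally supplied value as an
option. Pair distances are 2-D Euclidean in the sagittal plane within a
window (depth differences inside the thin window are ignored). The
active-vs-all distance comparison uses the Mann–Whitney U test — exact
null when both samples have ≤25 values and no cross-sample ties,
normal approximation with tie correction otherwise. The expected
distance CDF carries a pointwise 99.9% envelope from ≥10,000 subsets of
the all-pair pool, drawn without replacement at the active-pair count.

## 4. Spatial randomness test (`spatial`)

The statistic is the mean nearest-neighbour distance of the map. The
null is simulated: N (default 10,000) uniform patterns of the same
point count in the same bounded rectangle. With r_lo / r_hi the number
of replicate means ≤ / ≥ the observed mean,

p = min(1, 2 · (min(r_lo, r_hi) + 1) / (N + 1)).

The add-one convention avoids p = 0 from a finite simulation; direction
is "clustered" when the observed mean lies below the null median. No
edge correction is applied — observed and simulated patterns share the
identical region, so boundary effects cancel by construction.

Regions follow the experiment type: in vivo, the stained-and-imaged
area (or the bounding rectangle of the points when the irregular
outline is unavailable — an approximation, noted here); slices, the
bounding width of the labelled fibres times the molecular-layer
thickness. An `area_multiplier` of 2 re-runs the test in a
doubled-area, aspect-preserving region: a clustering verdict that
survives the doubling cannot be an artefact of too tight a region
(regular-spacing verdicts may legitimately weaken, since a larger
empty margin makes uniform patterns sparser).

Multi-window maps are stitched by translating each window by its 3-D
stage offset (sagittal components) and merging cross-window duplicates
closer than 1 μm — below any inter-fibre distance of interest.

Calibration, measured: type-I error 0.044 over 1,000 CSR patterns
(n = 15, 56 × 150 μm, 2,000 replicates each); power ≥ 0.99 with correct
direction on Thomas-cluster patterns (5 parents × 3 offspring,
σ = 3 μm) in the same region.

## 5. Coupling analysis (`coupling`)

For a within-window pair, the Pearson correlation of the two binary
raster rows equals the φ coefficient of the 2 × 2 contingency table
(checked as a property test). The two-sided p-value — the pair's
probability of independence — comes from the t-distribution on
n_trials − 2 df, matching common practice; a seeded permutation option
(≥10,000 shuffles) exists because trial counts can be small, and the
binary permutation null is discrete, so mid-range p-values can differ
between the two methods even when both are valid. Pairs with a fibre
responding on zero or all trials have undefined r; they are flagged
*indeterminate* and excluded from the coupled-fraction denominator
rather than silently counted as independent. No multiple-comparison
correction is applied across pairs; the number of tests is reported
instead. The distance analyses (Spearman rank correlation of
independence-p against pair distance; Mann–Whitney of coupled vs
independent pair distances; independent pairs vs all labelled pairs)
flag degenerate inputs (constant p or constant distance) instead of
returning undefined statistics.

Measured calibration: 10,000 independent Bernoulli(0.3) pairs at 200
trials give a coupled fraction of 0.047–0.051 across seeds, inside the
binomial band around the nominal 0.05.

## 6. Density calibration (`density`)

A 1 μm section along fibres with boutons every s = 3.7 μm intersects a
fraction t/s of boutons, so

labelled-fibre density = bouton density × s / t,
labelled fraction = labelled-fibre density / PF density.

The total PF density default is 5.5 μm⁻², the midpoint of the published
5–6 range; all parameters are exposed. Sections thicker than the bouton
spacing would cut a fibre at several boutons and are rejected. The
expected labelled count per Purkinje cell is fraction × 150,000,
rounded to the nearest integer; direct counts are compared with a
one-sample t-test. An empty map yields fraction 0 with a warning; a
fraction ≥1 is an error (implausible labelling). When several regions
are imaged, the fraction can be computed per region and averaged or
pooled; both reductions are trivial on the returned estimates — the
estimator itself is per-map.

## 7. The synthetic experiment generator (`synthetic`)

The generator emulates the statistical structure of the in vivo
recordings so every stage can be validated against known truth:

| quantity | default | rationale |
|---|---|---|
| imaging window | 56 × 150 μm | sagittal window × molecular-layer depth |
| fibres per window | uniform 4–21 | observed range, median ~13 |
| responder probability p_response | 0.028 | fraction of labelled fibres responding |
| trial response rate of a responder | 0.5 | free parameter; not constrained by the source recordings |
| spontaneous rate | 0.4 Hz in 19% of fibres | observed spontaneous activity |
| burst size | {1: .05, 2: .40, 3: .45, 4: .10} (mean 2.6) | "two or three events", mean 2.6 |
| intraburst ISI | uniform [1/172, 3/172] s | max burst frequency 172 Hz; ISI law otherwise unconstrained |
| latency | 0.5·N(10, 2²) + 0.5·N(22, 3²) ms | two sharp peaks; only locations reported |
| amplitude | N(0.5, 0.25²) ΔF/F, floor 0.05 | yields event SNR ≈ 7 over 0.07 noise |
| noise | N(0, 0.07²) ΔF/F | SNR 6.9–8.5 regime |
| frame rate / τ | 32 Hz / 0.4 s | population imaging; indicator decay |

**Point patterns.** CSR is i.i.d. uniform. "Regular" is a square-ish
lattice filling the region with uniform jitter of ±10% of the spacing
(a tendency toward regular spacing without a specific mechanism), with
a 1 point/μm² density cap. The Thomas process draws parents uniformly
and displaces offspring by isotropic Gaussians (σ default 3 μm);
offspring falling outside the region are re-drawn from the same parent,
which keeps the count exact at the cost of slightly pulling
border-parent clusters inward — negligible for σ ≪ region size.

**Shared-driver model.** A common mossy fibre is modelled as a
Bernoulli driver at two levels. A unit downstream of a driver with
rate q and per-unit reliability r, plus an independent background
channel b, has marginal p = q·r + b(1 − q·r); given a target marginal
the generator solves b = (p − q·r)/(1 − q·r), and with q unspecified
routes everything through the shared channel (q = p/r, b = 0). This is
applied once at the fibre level (is the fibre a responder at all,
marginal p_response — this is what the binomial/χ² analysis sees) and
once at the trial level among responders of the same group (marginal
`trial_response_p` — this is what the coupling analysis sees).
Non-responders contribute all-false raster rows. The split matters:
p_response is a *fibre-level* fraction; treating it as a per-trial rate
would make nearly every fibre a responder somewhere in a 40-trial
protocol and destroy the binomial null it is meant to parameterise.

**Traces.** Each spike adds an instantaneous-rise, exponential-decay
transient; amplitudes below 0.05 ΔF/F are clipped to the floor so
every simulated event is detectable in principle.

**What the generator does not emulate.** No optics or point-spread
function, no movie registration or segmentation errors, no indicator
saturation or dye bleaching, no correlated (photon/motion) noise, no
depth attenuation, no granule-cell biophysics. Passing tests therefore
demonstrate the *statistical* machinery is correct and calibrated under
the stated noise model — not that the detector is robust to every
artefact of real two-photon data.

## 8. Numerical conventions

* Lengths μm, times s, intervals half-open [start, end); coordinates in
  a right-handed sagittal frame, origin at the region's lower-left.
* Every stochastic routine takes a seed or an explicit NumPy generator;
  equal seeds give byte-identical outputs. The CLI logs package
  version, seed, and a configuration hash.
* CSV files are written with 17-significant-digit floats and read with
  round-trip parsing, so write→read is lossless for float64.
* The YAML configuration is validated against the known key set;
  unknown keys are an error naming them.
* Monte Carlo replicate counts: 10,000 for reported spatial p-values
  (resolution 2 × 10⁻⁴ two-sided); validation suites use 2,000
  replicates per test and hundreds-to-thousands of replicate
  experiments, sized to keep the full validation run in tens of
  seconds on one core.

## 9. Known limitations

* The coupling p-value's t-approximation is anti-conservative for very
  small trial counts; use the permutation option below ~20 trials.
* The in vivo region convention approximates the irregular
  stained-and-imaged outline by a rectangle; a too-generous region
  biases the CSR test toward "clustered", which is why the doubled-area
  robustness check exists.
* Stitching merges duplicates greedily in index order; for maps where
  genuine fibres sit within 1 μm of each other at window borders the
  tolerance must be lowered.
* The trial-level response rate of responders (0.5) is a free
  parameter; coupling power depends on it, calibration does not.
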
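# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data generator, and the numerical and design choices behind
`massresponse`.

## Response metric

Buoyant-mass samples are compared with the Earth Mover's Distance
(Wasserstein-1).  In one dimension the EMD between equal-size samples is
attained by the order-statistic pairing, `EMD(X, Z) = Σ|X₍ᵢ₎ − Z₍ᵢ₎|`
(`emd_sorted_equal`; its optimality is verified in the tests against
brute-force minimum-cost matching over permutations).  For unequal sizes
`emd_general` evaluates the CDF-integral form via
`scipy.stats.wasserstein_distance` and multiplies by `|Z|` so the two
definitions agree exactly whenever both apply.  The **mass response**
`MR(X) = EMD(X, Z)/ΣZᵢ` is therefore the per-cell transport distance as a
fraction of the mean reference cell mass.  Key exact identities, all
enforced by tests: `MR ≥ 0`, `MR(kX, kZ) = MR(X, Z)`, and
`MR((1+s)Z, Z) = |s|`.

The batched statistic used inside the bootstrap machinery evaluates the
unequal-size case on the fixed union grid of the two samples' quantile
levels, which makes the BCa jackknife (sizes n and n−1) vectorizable; it
matches `scipy.stats.wasserstein_distance` to machine precision.

## Experiment design and the test

A session is reference `Z` (vehicle, first) → test conditions `X` →
control `Y` (vehicle, last).  `MR(Y)` measures treatment-independent
phenotypic drift plus finite-sample noise; `θ = MR(X) − MR(Y)` is the drug
signal in excess of it.  Because trivially small distribution differences
become statistically significant at thousands of cells, the null is
non-zero: `H₀: θ ≤ θ₀` with θ₀ the limit of decision.

The test is a one-sided embedded (nested) bootstrap-t:

1. `S` = sample SD (denominator r−1) of θ over `r_inner` joint resamples
   of (X, Y, Z), each sample resampled independently within itself with
   replacement, sizes preserved;
2. `t_obs = (θ̂ − θ₀)/S`;
3. for each of `R_test` outer replicates, resample (X*, Y*, Z*), compute
   θ̂* and its own inner-bootstrap `S*`, and form `T* = (θ̂* − θ̂)/S*`;
4. `p = (1 + #{T* ≥ t_obs})/(1 + R_test)` (ties counted with ≥).

Studentizing each outer replicate by its own inner bootstrap is what makes
the pivot's distribution approximately parameter-free; the cost is
`R_test × r_inner` statistic evaluations, handled by sorting resample
*indices* rather than values (a resample of a sorted sample is sorted by
construction once its indices are).  Each outer replicate consumes an
independent RNG substream spawned from the master seed, so results are
bit-reproducible and independent of evaluation order.  A degenerate outer
replicate (`S* = 0`, essentially impossible for continuous data) maps to
`T* = ±∞` by the sign of its numerator; a degenerate `S` for the observed
data is an error naming the zero-variance cause.

### Parameters (`InferenceConfig`)

| parameter | default | meaning |
|---|---|---|
| `theta0` | 0.03 | limit of decision (fraction of mean reference mass) |
| `alpha` | 0.05 | significance level of the one-sided test |
| `N` | 2500 | cells per sample used for inference; larger samples are subsampled (seeded, without replacement), smaller ones used whole with a low-n flag |
| `R_test` | 999 | outer replicates → p-value floor 1/1000 |
| `r_inner` | 19 | inner replicates for each standard error |
| `R_ci` | 5000 | bootstrap replicates of the signal CI |
| `ci_level` | 0.90 | CI level (0.95 supported) |
| `ci_method` | bca | `bca` or `percentile` |
| `drift_limit` | 0.10 | control signal above which every call is inconclusive |
| `min_n` | 100 | low-n warning threshold |

The defaults for N, R_test, r_inner and R_ci reflect standard practice for
this assay: N = 2500 keeps the same-population baseline noise of MR below
1.5% (mean) / 1% (SD), and θ₀ = 3% is three sigma of the 500-cell
resampling distance (`decision_limit` recomputes it from any measured
population; the 3% default is reproduced by the default generator).  Two
conventions coexist in the field for the reported CI level (90% vs 95%);
both are supported, 90% is the default.

The drift rule is deliberately a *veto*, not a correction: if
`MR(Y) > drift_limit` the call is `inconclusive` regardless of p, since a
session that drifted more than 10% cannot resolve the ~5% responses the
limit of decision is designed around.

### Calls and multiplicity

`response` iff `p < alpha` (and no drift veto), else `no_response`.
p-values are per-condition by design — each drug is its own decision — but
the report includes a clearly-labelled Benjamini–Hochberg adjusted column
(via statsmodels) as optional metadata.

## Confidence intervals

Signal CIs use the bias-corrected and accelerated (BCa) bootstrap,
delegated to `scipy.stats.bootstrap` with both samples resampled
independently.  Known limitation: near the null (two samples from the same
distribution) the distance statistic is biased upward under resampling —
nearly all replicates exceed the point estimate — so the bias correction
saturates and the BCa interval collapses toward the point estimate.  This
affects only near-zero signals, where the interval is not decision-relevant
(the test, not the CI, makes the call); `ci_method="percentile"` avoids the
pathology at the cost of first-order accuracy.  Zero-variance samples
return a zero-width interval rather than an error.

## Curation

Measurement records carry a particle class (`intact`, `permeable`,
`aggregate`, `debris`, `unclassified`) from any labelling source.  The
default policy analyzes intact + permeable single cells — permeability is
a viability readout, not a rejection criterion — and rejects the rest; a
strict intact-only policy exists.  Curation never alters mass values.
Classifier imperfection is emulated, not learned: `ConfusionSpec` draws
observed labels from per-class row-stochastic confusion rows, retaining
the truth so precision/recall can be scored (metrics with empty
denominators are omitted, not zeroed).

The benefit of curation is quantified as *sampling error*: the SD of
`MR(subset, reference)` across random fixed-size subsets (1000 cells × 100
draws by default) of one condition.  Both mean and SD are returned; the SD
is the dispersion metric used in the paired curated-vs-uncurated property
test.  On populations contaminated with 20% aggregates + debris, curation
reduces this metric in ≥95% of paired seeds.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
not cell biology:

* **Baseline**: intact-cell mass is lognormal with arithmetic mean 60 pg
  and CV 0.35.  The lognormal family captures the right skew of real
  single-cell mass data; the CV was fixed (before any acceptance
  measurement) so that the 500-cell same-population noise lands at the
  canonical 3% mean / 1% SD and the 2500-cell noise under 1.5% / 1%.
* **Classes**: permeable cells are intact draws × 0.5 (membrane-compromised
  cells lose about half their dry mass), aggregates are sums of 2–3 intact
  draws, debris is lognormal with mean 8 pg and CV 0.8.  This reproduces
  the characteristic class-mean ordering aggregate > intact > permeable >
  debris.
* **Sensor noise**: additive Gaussian, 0.5 pg SD (typical instrument mass
  precision), floored at 0.01 pg.
* **Drug mechanisms** (`MoaEffect`): G1/G2 arrest = linear contraction of
  each mass toward the rescaled mean (mean × scale, CV × spread; defaults
  0.75/0.6 and 1.4/0.6) — consolidation around the arrested-stage mass;
  catabolic/anabolic = pure mean scale (0.90 / 1.10); membrane loss = an
  affected fraction relabelled permeable at 0.35× mass (a well-separated
  low mode); uniform shift ×(1+s) as the analytically exact reference
  effect.
* **Mixtures**: `mix_populations` draws defined fractions from treated and
  untreated populations; the response is linear in the responding fraction
  (R² > 0.99 in the acceptance suite).  Additivity of combination effects
  holds for same-direction effects; opposing shifts partially cancel in
  the transport coupling — a property of W1, not an artifact.
* **Drift**: multiplicative and linear in time, `mass × (1 − rate·t)`,
  applied to every particle at its measurement time; reference at t = 0,
  tests staggered, control at session end (3 h default).

What the generator does **not** emulate: cell-cycle structure and growth
dynamics, instrument-to-instrument offsets, correlated (non-iid) sampling
within a session, dose–response shapes, or death-induced count loss.
Passing tests therefore demonstrate the statistics' behavior under the
assumed sampling model, not performance on any particular real specimen.

## Problem sizes used in the test and acceptance runs

Simulation-heavy checks use the protocol sample size N = 2500 where the
claim depends on it (noise bounds, limit of decision, type-I/power
calibration) with 1000 pair draws for noise estimates; the calibration
study runs 200 null and 100 power replicates at a reduced R_test = 199
(the p-value floor 0.005 is still well below α = 0.05).  Unit tests that
only exercise logic use smaller fixtures (N ≈ 600–900), where a 10% shift
deliberately sits near the decision margin — fixtures there use larger
effects.

## Design choices where the design was open

* **Resampling unit**: cells within each of X, Y, Z independently, sizes
  preserved (no pairing structure exists across samples).
* **`decision_limit` pairs**: independent subsample pairs by default
  (population reused across pairs), disjoint pairs behind a flag; the two
  agree within Monte-Carlo scatter.
* **Pooling**: multi-instrument replicates of one condition are analyzed
  per instrument (each against its own reference); pooling is the caller's
  decision, not a default.
* **Missing role on ingestion** defaults to `test` with a warning;
  unknown class strings map to `unclassified` (rejected by the default
  policy) with a warning; invalid rows are rejected and counted, not fatal.
* **File formats**: delimited text with an explicit documented schema and
  a user mapping override; masses always picograms, no unit detection.
  Round-trips preserve float values bit-exactly (repr on write,
  round-trip parsing on read).
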
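# massresponse

Functional drug-sensitivity calling from single-cell buoyant-mass
distributions.

Suspended-microchannel-resonator (SMR) instruments weigh individual live
cells to sub-picogram precision as they flow through a cantilever sensor.
Because most cytotoxic and cytostatic drugs change how cells accumulate
mass well before viability assays can see an effect, comparing the
buoyant-mass *distribution* of drug-treated cells against vehicle-treated
cells provides a rapid, drug- and malignancy-agnostic functional response
readout — usable even for the small, fragile cell numbers obtainable from
primary tumor specimens.  This package implements the statistics for that
assay: the response metric, its confidence intervals, the hypothesis test
that calls response versus no-response, curation of measurements by
particle class, and a synthetic-experiment simulator used for calibration
and validation.  It is aimed at statisticians and assay developers working
with single-cell mass (or other one-dimensional single-cell) measurements.

## The statistic

Each measurement session follows a sandwich design: a vehicle-treated
**reference** sample `Z` is measured first, drug-treated **test** samples
`X` follow, and a vehicle-treated **control** replicate `Y` is measured
last.  For sorted samples of `N` cells each, the **mass response** of a
sample `X` is the Earth Mover's Distance (Wasserstein-1) to the reference,
normalized by the total reference mass:

    MR(X) = EMD(X, Z) / Σᵢ Zᵢ = Σᵢ |X₍ᵢ₎ − Z₍ᵢ₎| / Σᵢ Zᵢ

a unitless fraction of the mean reference cell mass (reported as percent).
It is non-negative, scale-invariant, and equals `|s|` exactly when every
cell's mass shifts by the relative amount `s`.  Unequal sample sizes use
the CDF-integral form of the distance, rescaled to agree with the sorted
pairing at equal sizes.

The test statistic subtracts the drift/noise signal carried by the control:

    θ(X, Y, Z) = MR(X) − MR(Y)

and the decision targets a *non-zero null* — statistical significance alone
is meaningless with thousands of cells per condition, so θ is compared
against a **limit of decision** θ₀ = 3%, itself defined as three times the
standard deviation of the distance between repeated 500-cell subsamples of
one population.  `H₀: θ ≤ θ₀` is tested one-sided with an embedded
bootstrap-t: the pivot `T = (θ̂ − θ)/S` is studentized with an inner
bootstrap (r = 19 replicates) and its null distribution simulated with
R = 999 outer replicates, each carrying its own inner bootstrap, giving
p-values on the grid `k/(1+R)` with floor 0.001.  A run whose control
signal `MR(Y)` exceeds 10% is called *inconclusive* — the cells drifted too
much ex vivo for any call to be trusted.  Signal confidence intervals are
BCa bootstrap intervals (90% default).

## Worked example

Simulate a four-drug panel (2500 cells per condition, 15% aggregate/debris
contamination) and analyze it:

```sh
massresponse simulate --out session.csv --seed 42 --n 2500 \
    --conditions "STAUROSPORINE:membrane_loss:0.4,PALBOCICLIB:g1_arrest,VINCRISTINE:g2_arrest,INERT:none" \
    --contamination 0.15
massresponse run --input session.csv --seed 1 --out-dir out
massresponse report --report out/report.json
```

which prints:

```
INERT: TEST 0.74%  CTRL 1.07%  theta -0.33%  p=1.000  CI[0.7, 0.7]%  -> no_response
PALBOCICLIB: TEST 22.76%  CTRL 1.07%  theta 21.69%  p=0.001  CI[21.6, 23.9]%  -> response
STAUROSPORINE: TEST 24.73%  CTRL 1.07%  theta 23.66%  p=0.001  CI[22.7, 26.5]%  -> response
VINCRISTINE: TEST 35.84%  CTRL 1.07%  theta 34.78%  p=0.001  CI[33.4, 38.2]%  -> response
```

`TEST` is each drug condition's mass response against the reference,
`CTRL` the control-vs-reference signal (here ~1%: no meaningful drift),
`theta` their difference, and `p` the embedded-bootstrap p-value against
the 3% limit of decision.  The three active mechanisms — permeabilization
(mass collapse of an affected fraction), G1 arrest (consolidation below
the mean), G2 arrest (consolidation above it) — are all called responses
at the p-value floor, while the inert condition sits at the noise level.
The same analysis is available in Python via
`massresponse.run_pipeline("session.csv")`.

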
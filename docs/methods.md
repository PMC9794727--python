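# Methods

`dspscreen` implements the analysis chain of an ex vivo drug sensitivity
profiling (DSP) platform: patient-derived tumor cells are screened as 3D
spheroids against a clinically focused library of 75–78 anticancer drugs
in 384-well plates, and the metabolic-activity readout (CellTiter-Glo-type
luminescence) is turned into per-drug sensitivity scores, cohort ranks and
a tumor-board style hit report. Because raw patient screen data are not
distributable, the package ships a first-class synthetic screen generator
that reproduces the statistical structure the pipeline assumes; every
stage is tested against it and against independent numerical oracles.

## Screen design

Each sample is screened on up to three 384-well plates. Every library
drug occupies ten wells: five concentrations spanning five orders of
magnitude (10× steps, default 1 nM – 10 µM) in duplicate. Each plate
carries three control treatments:

| control | treatment | role | default wells/plate |
|---|---|---|---|
| minimum effect | DMSO vehicle | 0% inhibition anchor | 16 |
| maximum effect | benzethonium chloride | 100% inhibition anchor | 16 |
| intermediate | 250 nM staurosporine | sublethal monitoring only | 8 |

The paper-scale library does not state how drugs partition over plates or
where controls sit; the defaults here place 26 drugs per plate (row-major
in rows B–O, columns 2–23), DMSO in column 1, benzethonium in column 24
and staurosporine in row A. All of this is configurable; the analysis
itself never depends on well positions. A screen is *full* when all three
plates pass QC, *partial* with one or two, *failed* with none.

## Normalization and robust Z′

Percent inhibition is anchored to the per-plate control means:

    inhibition = 100 · (count − mean_DMSO) / (mean_benzethonium − mean_DMSO)

Values are deliberately not clipped: growth stimulation gives negative
inhibition, over-killing gives >100%, and the curve fit absorbs both. The
formula is affine-invariant — rescaling every count on a plate (gain
changes, reagent lots) changes nothing downstream.

Plate quality uses the robust Z′,

    Z′ = 1 − 3 · (mad_pos + mad_neg) / |median_neg − median_pos| ,

computed from control *medians* and *robust dispersions* so single
outlier control wells cannot sink a plate. "mad" is the median absolute
deviation scaled by 1.4826 (consistent with σ under normality); raw
median-AD and mean-AD are available through `MadConvention`. The pass
threshold defaults to 0.5, the conventional excellent-assay cutoff; no
printed threshold exists to copy. Note the deliberate asymmetry:
normalization uses control means (that is how the normalization formula
is written), QC uses medians/MADs.

## Dose–response model

Responses are fitted on the log10 molar axis with the five-parameter
asymmetric logistic (5PL),

    y(x) = y_min + (y_max − y_min) / (1 + 10^(slope·(log10 EC50 − x)))^s ,

slope > 0, asymmetry exponent s > 0 (s = 1 is the symmetric 4PL). Box
bounds keep fits interpretable while tolerating unclipped data:
y_min ∈ [−30, 30], y_max ∈ [0, 120], slope ∈ [0.1, 10], s ∈ [0.2, 5],
log10 EC50 within the tested range ± 2 decades. R² is computed against
all replicate points (not per-concentration means). Flat data (zero
spread) short-circuit to a constant fit with R² = 1 by convention. Drugs
need ≥ 4 distinct concentrations on QC-passing plates to be evaluable;
with exactly 4, s is fixed at 1.

Optimization is a projected Levenberg–Marquardt, vectorized over problems
so that all drugs of a sample and all starts solve in a single batched
pass (a 78-drug sample fits in ~0.2 s on one core). Initialization is
deterministic multi-start: four EC50 candidates (the tested concentration
whose mean response is nearest 50%, the range midpoint, and the midpoint
± 1 decade), best SSE wins, ties broken by the asymmetry exponent closest
to 1. The fitter reproduces noise-free generating curves to machine
precision whenever the transition sits inside the tested window. When
the EC50 lies at or beyond the window edge, the five parameters are no
longer jointly identifiable from five distinct doses — near-interpolating
parameter sets exist along an extremely flat valley, and no optimizer can
pick the generating one from the data. Integral summaries (DSS, maximal
effect, inhibition at Cmax) remain accurate in that regime; individual
parameters (EC50, s) do not, which is exactly why scoring and hit calling
are built on the former.

Derived quantities:

- **predicted inhibition at Cmax** — model evaluated at the clinical peak
  plasma concentration; if Cmax falls outside the tested range the value
  is an extrapolation and the report flags `cmax_outside_range` instead of
  suppressing the drug;
- **absolute ICx** — closed-form inversion of the model at x% inhibition
  on the normalized scale, reported only within the tested range; a curve
  sitting above x% across the whole range is censored at the lowest tested
  concentration (the target is attained at or below it);
- **maximal effect** — the fitted value at the top tested concentration
  (the model is monotone), reported alongside the maximal observed
  per-concentration mean.

## Drug sensitivity scores

DSS integrates the fitted curve above an activity threshold t (default
10%) over the tested range and normalizes by the maximal attainable area:

    DSS = 100 · ∫ max(min(y(x), 100) − t, 0) dx / ((100 − t) · (x_max − x_min))

computed by adaptive quadrature with explicit splits at the threshold and
100% crossings. The integrand cap at 100% keeps scores on a 0–100 scale
even when the fitted asymptote overshoots. The absolute scale of this
variant need not match other published DSS flavors; all cross-sample
logic (quantiles, hit calls, dcDSS) is scale-consistent because every
sample is scored identically.

- **sDSS** = DSS − mean DSS of a healthy/nonmalignant control panel for
  the same drug (arithmetic mean by default, median by option). Negative
  values — drugs more active on normal cells than on the tumor — are kept
  visible, not floored.
- **dcDSS** = DSS(drug + anchor) − DSS(drug alone), the anchored
  combination score. The anchor is dispensed at its own IC25, computed
  from the anchor's monotherapy curve; no Bliss/Loewe surface modeling is
  attempted.

## Cohort context and hit calling

A sample's response to a drug is ranked as a quantile: the percentage of
*other* cohort samples with strictly lower DSS for that drug (ties do not
count; the sample is excluded from its own comparison set; quantiles are
reported only when the cohort holds ≥ 10 samples). A drug is a hit when
all of the following hold:

1. sDSS > 0 (the adjustment criterion has no published numeric cutoff;
   "more sensitive than healthy controls" is operationalized as strict
   positivity);
2. maximal fitted effect ≥ 75% inhibition;
3. absolute IC50 < Cmax, and predicted inhibition at Cmax ≥ 50% (both
   potency-at-exposure readings are evaluated and shown);
4. curve fit R² ≥ 0.8;
5. cohort quantile ≥ 75% (a required conjunct by default;
   `quantile_required=False` demotes it to advisory);
6. the drug is approved or in clinical studies. Investigational drugs are
   never reported as hits; when one passes all effect criteria it is
   attached to same-class hits as in-class support.

Improving any single metric can never turn a hit into a non-hit (all
criteria are monotone thresholds). Reports rank hits by quantile
(alphabetical on ties), flag hits with DSS < 5, carry the full waterfall
ordering (descending DSS, strongest drug first) and state explicitly when
no drug qualifies.

Heatmap orderings for drug-subset views (e.g. MDM2 inhibitors vs cohort)
come from agglomerative hierarchical clustering of the quantile sub-matrix
(Euclidean distance, complete linkage, deterministic leaf order).

Paired screens of the same tumor (fresh-tissue culture vs long-term
culture) are compared with Bland–Altman limits of agreement: bias =
mean(a − b), LoA = bias ± 1.96·SD(a − b) with the n−1 sample SD; pairs
outside the LoA are flagged as outliers.

## Synthetic screens and what they do (not) show

The generator inverts the normalization exactly: a drug well's expected
count is `floor + (baseline − floor) · (1 − y_true/100)` with baseline =
DMSO level (default 1e5) and floor = benzethonium level (default 5e3),
multiplied by lognormal noise of constant CV (default 5%, the right noise
family for luminescence readouts; additive Gaussian is available for
robustness checks). With zero noise, normalize ∘ simulate is the
identity at every well, which pins down the whole chain's correctness to
machine precision.

Default study conditions: 40 samples × 78 drugs, three plates per sample,
three planted sensitive pairs per sample. Planted hits draw
y_max ~ U[80, 100] and log10 IC50 1–2 decades below the drug's Cmax, so
they satisfy every hit criterion with margin; the remaining pairs draw
y_max ~ U[0, 40] and fail the maximal-effect criterion by construction.
Each drug's Cmax is the 4th tested concentration ± 0.5 decade, so the
IC50-below-Cmax criterion is exercised on both sides. Planted hits land
only on reportable drugs and are capped per drug so each stays in its
drug's top cohort quartile. The healthy-control panel is simulated as
null-parameter DSS draws, making sDSS ≈ DSS for planted hits. Control
degradation modes (`pos_drift`, `neg_scatter`, `separation_loss`) damage
the control wells in three distinct ways, each pushing Z′ below 0.5 at
default strength.

What passing tests show: the numerics (normalization, Z′, fitting, DSS,
quantiles, LoA) are correct against independent oracles, and the decision
chain recovers planted truths at realistic noise. What they do not show:
robustness to spatial plate artifacts (edge effects, drift — no B-score
or LOESS correction is implemented), non-lognormal noise, cell-growth
kinetics, or any pharmacology; the generator is statistical, not
biological.

## Problem sizes and numerical choices

Tests and the acceptance script use the default cohort (40 × 78, seeds
1–10 for the recovery check), 100–200 random curves for oracle
comparisons, and 1000 pairs for LoA coverage — sizes chosen so the whole
suite replays on a single core in minutes while keeping every estimate's
Monte-Carlo error far below the asserted tolerances. Quadrature runs at
1e-10 absolute/relative tolerance with kink splits; ICx inversion is
closed-form; all simulation randomness flows from named, CRC-keyed
substreams of one seed, so every artifact is a pure function of
(config, seed) and byte-identical across processes.

## Known limitations

- The DSS scale is this package's variant (threshold-excess area,
  clipped at 100%); absolute values are not comparable to other DSS
  implementations, only rank/contrast logic is.
- Single 5PL parameters are unreliable when the response transition is
  not bracketed by the tested concentrations (see above); consumers should
  use DSS / ICx / max-effect, which is what the hit logic does.
- No secondary QC criteria beyond robust Z′ are implemented; the QC
  classification is single-statistic.
- Quantiles need ≥ 10 cohort samples; below that the quantile criterion
  cannot pass (by design, reported as missing).
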
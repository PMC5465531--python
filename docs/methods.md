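# Methods

## Scope and model

The package implements the statistical chain of a two-method cardiac output
(CO) comparison: derivation of CO from raw echocardiographic and
thermodilution measurements, Bland–Altman agreement with percentage error,
replicate-based precision and least significant change, four-quadrant and
half-circle polar trending analysis of 24-hour changes, and ROC-based change
detection. A synthetic cohort generator with a matching analytic oracle
closes the loop: every statistic the pipeline reports can be checked against
the value implied by a known generative model.

## Measurement derivation

Echo CO uses the standard LVOT/Doppler construction: the LVOT is assumed
circular with diameter the mean of repeated measurements (nominally 3), so
`area = π (d̄/2)²`; stroke volume is area × mean VTI (nominally 5 beats,
cm³ ≡ ml); CO = SV × HR / 1000 in L/min. Full-precision π is used; sources
that print the formula with the rounded constant 3.14 can be matched
bit-for-bit via `pi_literal=3.14`. PAC CO is the arithmetic mean of the
bolus series (nominally 5). Off-nominal replicate counts are accepted —
real data are messy — but logged as warnings; non-positive values are
rejected outright.

## Precision convention

No universal formula exists for "precision" of an averaged replicate series;
the hemodynamic-monitoring literature most often uses

    precision% = 100 · k · CV / √n,  k = 2,

where CV is the within-subject coefficient of variation of single replicates
(sd with the n−1 denominator, divided by the subject mean) and n the number
of replicates averaged into the reported value. Subject CVs are pooled as a
root mean square, so the pooled CV² is the mean within-subject relative
variance; arithmetic-mean pooling is available (`pooling="mean"`), as is
k = 1.96. The least significant change is `precision · √2`, the threshold a
measured change must exceed to be distinguishable from noise of two
independent averaged measurements. These conventions are configurable
because published reports are not always internally consistent under any
single convention (an 8% precision implies an 11.3% LSC under √2, yet
precision 8% and LSC 9% are sometimes reported together); the package makes
the chosen convention explicit and serialises it into every report.

## Agreement

Bias is the mean difference (test − reference) by default. A
`central_tendency="median"` option reports the median difference instead —
some papers write "median bias" — but the limits of agreement are always
`mean ± 1.96·sd` of the differences: that is the only construction
consistent with a symmetric interval, and the option therefore moves the
bias line only. Percentage error follows Critchley and Critchley: the LOA
half-width divided by the grand mean of the pairwise mean CO (not the
reference mean; that variant exists behind `pe_denominator="reference"`).
Repeated measurements per patient are treated as independent pairs, as such
studies conventionally do at this scale; no mixed-effects LOA correction is
attempted.

## Trending

Percentage changes use each method's own first measurement as baseline.
The four-quadrant exclusion zone is the open central square: a pair is
excluded iff **both** |%Δ| are strictly below the zone (default 15%) — a
pair with a large reference change and a tiny test change is data, not
noise, and stays in. A zero change in either method counts as discordant
(it agrees with no direction). The polar transform maps a change pair
(Δref, Δtest) to angle `atan2(Δtest, Δref) − 45°` — the identity line
becomes the polar axis — and radius `|Δref + Δtest| / 2`; pairs with a
negative mean change are folded by 180° into the half circle, so concordant
decreases lie on the axis like concordant increases. The polar exclusion
zone removes radii below 0.5 L/min, boundary points kept (the source
conventions are silent on the boundary; keeping it is documented here and
immaterial for continuous data). Radial LOA are parametric,
mean ± 1.96·sd of included angles, matching the symmetric intervals such
studies print; an empirical 2.5/97.5-percentile option exists. Angles are
summarised by ordinary (not circular) statistics — after folding, the
angles of any usable trending dataset live well inside (−180°, 180°], where
the linear mean is the accepted summary. Sets in which fewer than two pairs
survive an exclusion zone raise an explicit `UndefinedResultError` rather
than emitting NaN.

## Change detection

Labels come from the reference method (positive iff %ΔCO_ref > 10%,
strictly), scores are %ΔCO_test. The AUC is the trapezoid area under the
empirical ROC, computed via the rank (Mann–Whitney) identity with ties
counted half. The 95% CI uses the DeLong structural-components variance
(verified against R's pROC to 10 decimal places on a frozen dataset; a
stratified bootstrap is available), clipped to [0, 1]; the p-value tests
AUC = 0.5 with the same variance. Operating-point sensitivity/specificity
use the strict rule score > threshold (default 8%). The Youden-optimal
threshold is reported as a convenience field only.

## Generative model of the simulator

For patient i: true CO `T_i1 ~ N(μ_CO, σ_CO²)` truncated below at 1.5 L/min
by rejection (not clipping, which would distort the tail); for the
follow-up subset, `T_i2 = T_i1 · exp(N(δ_μ, δ_σ²))`. Each method m at each
timepoint sees a method-level value `T(1 + ε) (+ bias for the test method)`
with `ε ~ N(0, σ_method²)` drawn independently per method, patient and
timepoint — this is the day-level calibration disagreement between methods.
Replicates are drawn around the method-level value with per-replicate CV
(`cv_rep_ref` for boluses, `cv_rep_test` for VTIs). Echo raw values are
back-solved — diameter from a population distribution, VTI = SV/area —
so the measurement pipeline reconstructs the intended CO exactly when all
noise is zero. Two noise layers are essential: replicate noise at the 8–9%
precision level alone cannot produce limits of agreement of ±1.5 L/min;
the method-disagreement layer supplies the between-method scatter.

Defaults (chosen once, from the magnitudes such ICU cohorts report, and not
revisited): 38 patients, 26 with follow-up (64 pairs); μ_CO = 6.0,
σ_CO = 1.2 L/min; δ_μ = 0, δ_σ = 0.15 (≈ 26% of changes exceed +10%, a
realistic volume-response rate); bias = 0.2 L/min; σ_method = 0.075;
cv_rep_ref = 0.09, cv_rep_test = 0.10 with 5 replicates each (emergent
precisions ≈ 8.0% and 8.9%); LVOT diameter 2.0 ± 0.15 cm; HR 100 ± 18 bpm.
Under these defaults the emergent percentage error is ≈ 24–25% and the
change-detection AUC ≈ 0.79.

`expected_summaries` returns the model-implied statistics. Bias, difference
sd and PE are closed forms: with s = σ_method, h_m² = cv_m²/n_m, b = bias,
`Var(d | T) = T²[(1+s²)(2+h_ref²+h_test²) − 2] + (2bT + b²)h_test²` and
`E[d | T] = b`, so the marginal difference variance is the mixture mean of
the conditional variance over the t1/t2 CO distribution (truncated-normal
and lognormal moments supplied by scipy). Replicate precision expectation
is `100·k·cv/√n`. The change-detection AUC has no closed form once the
exact ratio-form percentage changes are used, so it is evaluated by
high-precision Monte Carlo directly on the generative equations (10⁶ draws,
own fixed seed, MC error ≈ 0.0006) — a code path independent of the cohort
generator.

## What the simulator does and does not emulate

It reproduces the *statistical* structure the analysis assumes: paired
design, two noise layers, replicate counts, a follow-up subset, skewed
multiplicative changes. It does not model beat-to-beat or ventilator-cycle
physiology, operator-dependent image quality, diameter-measurement error
correlated over time (the LVOT diameter is constant per patient, as it is
anatomically), or non-normal replicate noise. Passing recovery tests
therefore demonstrates that the statistics are computed correctly and that
the pipeline is unbiased under the assumed model — not that any particular
clinical dataset satisfies those assumptions.

## Numerical and design choices

* Exclusion-zone boundaries: four-quadrant zone is open (strictly inside
  excluded); polar zone keeps boundary radii.
* Correlation guards use exact element equality (matching scipy's constant
  check), since a constant column makes r undefined even when floating-point
  `std` is a nonzero 1e-16.
* Degeneracies are typed: `InvalidInputError` for precondition violations,
  `DegenerateDataError`/`UndefinedResultError` for statistics undefined on
  the data; the pipeline converts the latter into explicit
  `{"undefined": reason}` report entries and exit code 3.
* Determinism: cohorts are reproducible from (params, seed); analysis
  reports are bit-reproducible given input and config (no timestamps).
* Test problem sizes: recovery tests use 1000-pair cohorts for bias/PE/
  precision and a 2000-change-pair cohort for AUC — sizes at which the
  Monte-Carlo error of each statistic is several times smaller than its
  recovery tolerance; the whole suite runs in seconds on one core.

## Known limitations

* No repeated-measures correction in the Bland–Altman variance; with 1–2
  pairs per patient the impact is small, but LOA on heavily repeated designs
  would be anticonservative.
* DeLong CIs are asymptotic; at very small n (a handful of positives) the
  bootstrap option is preferable, and neither fixes the coarse empirical
  ROC.
* The polar radial LOA assume approximately normal angles; heavy-tailed
  angle distributions are better served by the percentile option.
* The precision convention (k, pooling, √2 LSC factor) must match whatever
  report you compare against — check the config echo in `report.json`.
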
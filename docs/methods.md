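# Methods

## Scope and model

The package analyses a two-treatment, two-period crossover comparison of
inhaled formulations in which the pharmacokinetic matrix is exhaled breath
condensate (EBC) rather than plasma, together with a cascade-impactor
characterization of the emitted aerosol. Three computational legs:

1. non-compartmental PK metrics from interval-collected concentration
   profiles;
2. paired TOST bioequivalence statistics on the log scale;
3. aerodynamic particle-size metrics from stage depositions.

## Interval profiles and PK metrics

EBC is collected over windows (default: six 4-minute windows at 0–4,
14–18, 28–32, 42–46, 56–60, 70–74 min after dosing), so each measurement
is an interval average rather than a point sample. A window is mapped to a
representative time before any time-weighted computation; the default is
the **midpoint** (the standard grid then runs 2–72 min), with `start` and
`end` conventions available for sensitivity analysis. For a constant or
linear profile the AUC is convention-invariant up to the span; for real
declining profiles the choice shifts AUC by well under the assay noise.

* **Cmax** is the maximum usable concentration; ties resolve to the
  earliest window. An all-missing profile is an error, not a zero.
* **AUC** uses the linear trapezoidal rule between representative times of
  usable windows only: no extrapolation to t = 0 or beyond the last
  window, so the quantity is AUC over the sampled interval. A missing
  interior window widens the spanning trapezoid and logs a warning.
* **Below-LLOQ values**: the default policy drops them (treated as
  missing); `half` (LLOQ/2) and `zero` substitutions are available. No
  policy is privileged by the data model — the flag is carried through and
  the choice applied at computation time.

## Crossover bioequivalence

The analysis is the paired subject-ratio construction: with one value per
subject per treatment, dᵢ = ln(testᵢ/referenceᵢ),

    GMR = exp(mean d),  CI = exp(mean d ± t₁₋α,ₙ₋₁ · sd(d)/√n),

with the sample sd (n−1) and α = (1 − ci_level)/2 (0.05 at the default
90% CI). The CI-inclusion rule against the 0.80–1.25 margin is equivalent
to the two one-sided tests procedure at α = 0.05; `tost_pvalues` exposes
the one-sided p-values and the equivalence of the two formulations of the
rule is exercised in tests. Margin comparison is inclusive. A full
crossover ANOVA with period/sequence effects is deliberately out of scope:
with one observation per subject-treatment and no published
period/sequence assignment, the paired construction is the estimable
model, and subject effects cancel exactly in the ratios. Zero-variance
data degrade to a point CI with a warning rather than an error, so
constructed identical-arm datasets remain analysable. Reports round to 3
significant figures; all internal arithmetic is double precision.

## Impactor APSD

The throat deposit is excluded from the sized distribution (it has no cut
size); the micro-orifice collector (MOC) is terminal — its mass counts
below every cut. For sized stages in decreasing cut order, the cumulative
percent-undersize at cut dᵢ is 100 × (mass on stages with cuts < dᵢ) /
(total sized mass).

* **MMAD**: diameter at 50% undersize, by linear interpolation of percent
  vs ln(d) between the bracketing stages (default), or by a least-squares
  probit(percent) vs ln(d) regression over all interior points.
* **GSD**: √(d₈₄.₁/d₁₅.₉) with the same interpolation. When both tail
  quantiles fall inside a single stage band (near-monodisperse aerosol)
  the spread is unresolved and an error is raised.
* **FPD**: sized mass below the 5 µm cutoff, reading the fractional share
  of the band containing the cutoff off the log-linear curve; expressed
  per actuation (default), per n-actuation dose, or per whole run.
* **FPF**: FPD as a percent of the metered dose (label claim × actuations)
  or of the total recovered (ex-device) mass — the default, since it needs
  no label-claim assumption.

Assay amounts given as concentrations convert to mass via the recovery
volume (mg/L × mL = µg; default 10 mL per segment). Cut sizes are taken as
stated at the experiment's flow rate; no flow-rate rescaling is applied.

**Known limitation — stage resolution.** Log-linear interpolation is exact
only where the underlying cumulative curve is log-linear. For a log-normal
aerosol with MMAD near 5 µm and a narrow spread (GSD ≈ 1.5), the 84.1%
quantile falls inside the wide 6.4–11.8 µm band of the standard cut set
and the interpolated GSD is biased high by ~11%; coarser still, when
MMAD × GSD exceeds the top cut the tail quantile is not bracketed at all
and estimation raises. Users with coarse, narrow distributions should
prefer the probit method, which pools the whole curve.

## Calibration and limits

Calibration is a straight line fitted by least squares, unweighted by
default with optional 1/x weighting (bioanalytical convention for ranges
spanning decades); r² is always the unweighted coefficient of
determination of the fitted line. Detection limits follow the
signal-to-noise convention LOD = 3σ_noise/slope, LLOQ = 10σ_noise/slope,
with σ_noise supplied by the analyst (peak-level signals are not
modelled). Precision is the sample CV, 100·s/x̄.

## Synthetic data generators

The EBC generator draws a subject baseline Cmax log-normally around a
geometric mean (default 17.5 ng/mL, between-subject CV 0.35), applies one
multiplicative log-normal within-subject error per administration (default
CV 0.30, giving sd(ln ratio) = √2·σ_w ≈ 0.42 — in line with the CI widths
an eight-subject study of this kind produces), and declines
mono-exponentially from the first window with a 45-min half-life, chosen
so the simulated AUC/Cmax ratio matches the bundled study's ≈ 43.5 min on
the 2–72 min grid. The test arm scales the baseline by the target Cmax GMR
and solves (Brent's method) for the test-arm half-life that makes the AUC
GMR hit its own target, so the two metrics' true ratios are controlled
independently. The generator emulates the monotone first-window-peak shape
and log-normal variability of real EBC data; it does not emulate absorption
lag, assay censoring at the LLOQ, or period/carryover effects, so passing
recovery tests demonstrate correctness of the statistics under the assumed
model, not robustness to those features.

The impactor generator partitions (1 − throat_fraction) of the total mass
into stage bands by a log-normal CDF in ln(diameter) (top band to ∞, the
terminal collector's band to 0), with optional multiplicative stage noise.
Defaults (MMAD 3 µm, GSD 2, throat fraction 0.78, 2200 µg over 10
actuations, 30 L/min) mirror the bundled runs.

`power_surface` estimates the probability of declaring BE over a grid of
(n subjects, true GMR) by direct simulation through the same TOST code
path; at a margin boundary this converges to the one-sided size (≈ 0.05).
Monte-Carlo sizes in the shipped tests (10,000 trials for size, 2,000 for
coverage) keep standard errors a few per mille while the whole suite runs
in seconds.

## Numerical choices

* All randomness flows through `numpy.random.Generator` seeded from
  configuration; identical seeds give byte-identical outputs.
* t quantiles, normal CDFs/quantiles, the Welch test and the probit
  regression come from `scipy.stats`; the trapezoid primitive is
  `numpy.trapezoid` (its test oracle is an independent fine-grid midpoint
  Riemann sum).
* Interpolation exactness: a cutoff or quantile landing exactly on a stage
  cut is returned without interpolation; GMR margin checks are inclusive.
* Degenerate inputs fail loudly (empty profiles, zero sized mass,
  non-positive metric values, degenerate calibrations) except where a
  degenerate answer is well-defined (zero-variance CI, zero-CV precision).
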
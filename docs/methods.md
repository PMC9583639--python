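# Methods

## Dose model and assumptions

Risk is assessed for one pathway only: accidental ingestion of surface
soil. Dermal contact, inhalation, dietary intake and bioaccessibility
adjustment are out of scope, as is any blood-lead (IEUBK-style) modeling
for Pb. The average daily dose is

    ADD = (C · IR · EF · ED · CF) / (BW · AT · 365 day/yr)

and the lifetime average daily dose replaces AT with the lifetime LT.
The year length in the normalization is fixed at 365 days; EF (350
day/yr) already absorbs any leap-day effect. Chronic scenarios set
AT = ED, so for a 75-year adult exposure ADD and LADD coincide and the
algebraic identity CR = HQ · RfD · SF holds — the test suite asserts it.

Hazard quotients are reported per element; they are deliberately not
summed into a hazard index, since the underlying assessment reports
per-element chronic risk only.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| IR (adult) | soil ingestion rate | 20 | mg/day |
| EF | exposure frequency | 350 | day/yr |
| ED = AT (adult) | exposure duration | 75 | yr |
| LT | lifetime | 75 | yr |
| CF | mass conversion | 1e-6 | kg/mg |
| BW (adult f/m/combined) | body weight | 74.7 / 87.7 / 80.8 | kg |

The adult body weights are *calibrated defaults*: Exposure Factors
Handbook adult means, back-calculated so the deterministic adult risks
reproduce published three-significant-figure values within 1%. Child
groups (newborn 6 wk–1 yr, 1–6 yr, 6–11 yr) use EFH central soil-only
ingestion rates (30 / 50 / 50 mg/day) and age-group mean body weights;
they are qualitative defaults with provenance notes and are overridable
(`ScenarioTable.override`). They are checked only qualitatively (e.g.
newborn arsenic HQ above 1), never against printed values.

The default oral toxicity table (RfD, SF) holds IRIS/RAIS values, e.g.
As RfD 3e-4 mg/(kg·day) and SF 1.5 (mg/(kg·day))⁻¹, Cr(VI) RfD 3e-3 and
SF 0.5, Pb SF 8.5e-3 (no RfD); Mn uses the soil-adjusted RfD 2.4e-2.
All constants are overridable through `ToxicityParams` or a YAML config
(`soilrisk.config`).

Total chromium is split 80/20 into Cr(III)/Cr(VI) before risk
calculation; the hexavalent fraction is a parameter of
`speciate_chromium` and `scenario_risk_table`.

## Probabilistic design

Monte Carlo trials draw (C, IR, BW) independently — no correlation
structure is assumed, though the sampling is isolated in
`FittedDistribution.sample` so a correlated sampler can be substituted.
The ingestion-rate lognormal interprets the stated "central tendency"
of 50 mg/day as the **median** (a mean of 50 with a 95th percentile of
200 has no real lognormal solution) and fixes the upper quantile at the
95th; both are arguments of `ingestion_rate_distribution`. Fixed
factors follow the probabilistic design: EF 350 day/yr, ED 75 yr,
AT 27,375 days (75 × 365). Age-resolved variability is *not* in the
Monte Carlo: the population is represented by one body-weight
distribution, so child subgroups appear only in the deterministic
scenarios.

Seeding: one master seed spawns independent substreams
(`numpy.random.SeedSequence.spawn`) per bootstrap repetition, making
repetitions independent and the whole computation reproducible from
(spec, seed). Non-finite or out-of-support draws are re-drawn for at
most 100 rounds; beyond that the simulation raises rather than return a
shortened trial vector. Bootstrap uncertainty re-runs the full
simulation (the published wording — the simulation "was repeated" —
supports re-running over resampling one trial vector) and reports the
SE and IQR of the per-repetition mean and median. When all repetition
statistics are bit-identical (point-mass specs) the spread is reported
as exactly zero instead of the rounding noise of a naive standard
deviation.

## Distribution fitting

Candidates for concentration data are lognormal, gamma and Weibull
(beta is reserved for bounded variables such as body weight). All fits
are maximum likelihood with the location pinned at zero; moment matching
is only a fallback if MLE fails to converge. The winner is chosen by the
smallest Anderson–Darling statistic, computed in-package for any fitted
CDF — AD is tail-weighted, which is what matters for risk; the exact
ranking rule of the commercial tool this emulates is proprietary, so AD
is this package's documented choice. Concentrations are fitted pooled
across site categories by default; per-category fitting is just a
filtered call. Normality testing (Anderson–Darling and
Lilliefors-corrected Kolmogorov–Smirnov, composite normal null) comes
from statsmodels.

## Statistics

Mann–Whitney comparisons are two-sided at α = 0.05, with the exact null
distribution of U (shift-algorithm recursion, own implementation) when
n_a·n_b ≤ 400 and the pooled sample has no ties, and the tie-corrected
normal approximation (scipy) otherwise. The exact two-sided p-value is
2·min(P(U ≤ u), P(U ≥ u)) capped at 1. Direction is reported post hoc
from rank sums only on rejection. No multiple-testing correction is
applied across the six category pairs by default (matching per-pair
reporting practice); a Holm adjustment is available but off. Rank
decisions are invariant under the strictly monotone concentration→dose
map, so testing exposures and testing concentrations are equivalent —
asserted in the tests.

Descriptive statistics use linear-interpolation percentiles
(numpy default) and the sample (n−1) standard deviation for the CV; a
single observation has CV 0 and a zero mean leaves the CV undefined
(`None`). Each table row is treated as one observation — the
granularity of compiled multi-study tables is ambiguous, and per-row is
the only convention that needs no extra metadata. Censored
(below-detection) records substitute half the detection limit.

## Synthetic data

The generator emulates the structure of a compiled national soil
survey: per (element, site category) lognormal groups with stated
medians and geometric SDs, plus an industrial "hotspot" mechanism that
multiplies a Bernoulli fraction (default 10%) of industrial draws by a
factor (default 5) to mimic extreme contamination near organized
industrial zones. The default Turkey-like spec reuses published urban
and industrial group means as synthetic *medians* (a fixture
convention, not a claim about the real data), derives suburban (0.9×),
agricultural (0.7×) and rural (0.5×, except arsenic's published
2.5 mg/kg) medians from urban, and keeps every group CV inside the
0.83–3.85 envelope reported for such surveys. It does **not** reproduce
the real compiled dataset, its fitted distribution parameters, province
geography, inter-element correlation, or measurement/censoring error —
so a green end-to-end test establishes that the pipeline is correct and
calibrated on data with the assumed shape, not that any specific
published Monte Carlo output is reproduced. Published simulation
summaries indeed depend on unpublished fitted concentration
distributions; the acceptance checks for the Monte Carlo stage are
therefore structural (point-mass collapse to the deterministic oracle,
independent moment oracle within 3 MC standard errors, 1/√n bootstrap
scaling, and zone classification of the published summary values).

## Numerical choices and edge cases

- Zone boundaries: HQ = 0.1 and HQ = 1 belong to the "investigate"
  band; CR = 1e-6 is safe, CR = 1e-4 is high priority (open intervals
  donate their lower edge to the safer zone).
- `speciate_chromium` returns `(total − cr6, cr6)` so mass is conserved
  to within one floating-point rounding.
- Exact Mann–Whitney with all pooled values identical returns p = 1
  (no information), not an error.
- Degenerate (constant) data are rejected by `fit_best` and
  `normality_tests`.
- The `point` distribution family is a package addition used to collapse
  the Monte Carlo onto the deterministic equations in tests.

## Known limitations

- Single exposure route; no hazard index across elements.
- The Monte Carlo body-weight distribution is adult-weighted; child
  risks exist only deterministically.
- Published child IR–BW pairs are unknown; child deterministic risks are
  indicative, not reproductions.
- The exact Mann–Whitney branch is O(n_a·n_b·(n_a+n_b)) per call and is
  capped at n_a·n_b ≤ 400 by design.
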
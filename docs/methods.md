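# Methods

## Model

Severity of a complex emergency (CE) is treated as a predictor of need
and decomposed, following the Utstein template, into vulnerability (the
population's preexisting susceptibility) and exposure (the magnitude of
the crisis impact). The default model scores eight values per country —
four vulnerability indicators and two exposure indicators each taken as
an absolute count and as a proportion of the total population — on a
three-tier scale, Low-Moderate (1), High (2), Critical (3). Tier values
sum within each component (4–12 when complete) and the two component
scores combine into one severity figure.

The functional form of the combination is genuinely open: the severity
logic is multiplicative in spirit (no vulnerability or no exposure means
no disaster), but a sum is easier to read and decompose. We default to
`sum` (severity 8–24) and offer `product` (16–144) by configuration;
both component scores are always reported alongside the composite so the
choice stays transparent. Indicators are equally weighted within a
component; there is no evidential basis for differential weights, and
weights would trade transparency for false precision.

Polarity is part of the model configuration: GNI per capita and adult
literacy are higher-is-better (low values are severe), under-five
mortality, underweight, affected and uprooted are higher-is-worse.

## Tier thresholds

Cut points are the 33.33rd and 66.67th percentiles (linear interpolation
between order statistics, inclusive endpoints) of a reference
distribution, computed per scored value. Vulnerability thresholds are
derived from a low-development reference set (~50 countries with
HDI < 0.5); exposure thresholds from an appeal-scale emergency set
(default 15 emergencies), mirroring the two data sources the model is
calibrated against. Equal-occupancy tertiles are the least-assumption
reading of a three-tier design; the `method` field on each threshold
records the derivation so hand-set cut points can be loaded from
JSON/YAML instead.

Band boundaries are half-open on the severe side: a value exactly equal
to a cut point takes the *less* severe adjacent tier. This is the
conservative convention with respect to scarce-funding claims and is
applied symmetrically under both polarities. Thresholds require at least
three reference observations per value; an all-identical reference is a
degenerate-distribution error, not a silent zero-width band.

Missing data are excluded from scores and flagged, never imputed — a
country is not made to look better or worse by absent statistics. The
`critical` missing-data policy is available for users who prefer the
conservative worst-case reading; either way `n_missing` and per-value
flags make the gap visible, and severity is unset entirely when a whole
component is unavailable.

## Indicator ranking

Candidate indicators are ranked 1–3 on three criteria, summed to a 3–9
total: evidence (3 points for support in at least three articles *and*
at least three existing indexes, 2 for at least two of each, else 1 —
both thresholds must hold at a level, since mixed cases do not
demonstrate the same consensus), timeliness (3 for context-driven or
sub-annual updates, 2 for annual, 1 for rarer), and availability (one
point above baseline for each of: presence in more than a third of
funding-appeal documents, presence in the World Bank database).
Selection is greedy by total score under a field-diversity constraint —
no thematic field contributes a second indicator while another field
with remaining candidates has none — with ties broken by evidence
points, then name. The tie-break is our convention; real selections of
this kind involve expert judgment that a rule can only approximate.

The packaged candidate table
(`data/candidate_indicators_synthetic.csv`) is a synthetic
reconstruction of a 25-candidate list: names and field tags only, with
evidence columns left blank for users to fill from their own searches.

## Synthetic data

The generator emulates the statistical setting the thresholds assume:
~50 low-development countries for vulnerability and 15 appeal-scale
emergencies for exposure. Defaults (all configurable, all synthetic —
chosen as plausible for low-HDI countries, not observed values):

| Indicator | Family | Parameters | Bounds |
|---|---|---|---|
| GNI per capita, PPP ($) | log-normal | median 1,400, σ 0.55 | [300, 6,000] |
| Under-five mortality (/1,000) | normal | mean 95, sd 35 | [25, 250] |
| Adult literacy (%) | normal | mean 55, sd 17 | [15, 95] |
| Underweight (%) | normal | mean 22, sd 8 | [3, 45] |

Truncation is by inverse-CDF, so bounds reshape the density rather than
piling mass at clip points; true means and tertiles of the truncated
families are available in closed form for calibration tests.
Populations are log-uniform over [1M, 80M]; the affected count is a
uniform fraction (2–60%) of the population and the uprooted count a
uniform sub-fraction (10–80%) of the affected, which guarantees
uprooted ≤ affected ≤ population by construction. All draws come from a
seeded generator; identical configurations give identical profiles and
byte-identical downstream reports.

What passing tests on synthetic data do *not* show: real indicator
values are serially correlated across neighbouring countries, reported
with heterogeneous lags and definitions, and missing non-randomly —
none of which the generator models. Tests establish that the machinery
is correct, not that the model is valid on real CE data.

## Numerical choices and problem sizes

- Percentiles: `numpy.quantile(..., method="linear")`, checked in tests
  against an independent sort-and-interpolate oracle. Linear-interpolation
  quantiles are permutation-invariant but only approximately invariant
  under replicating the reference list (the plotting position (n−1)q
  shifts with n); tests bound that drift by the bracketing order
  statistics.
- Ranking ties: evidence points descending, then name ascending —
  deterministic and documented rather than arbitrary.
- Country-ranking ties: exposure score, then vulnerability score, then
  name; incomplete results always sort last.
- Test problem sizes: tertile balance at n=50 (20 replicates),
  convergence to true tertiles at n=5,000 (2% relative), generator
  calibration at n=500 (3 standard errors), monotonicity over 1,200
  random profile/threshold cases. The whole suite runs in a few seconds.

## Limitations

- The tier encoding (1/2/3) and the sum combiner are conventions; the
  underlying framework prescribes neither, and alternative encodings
  change composite values (though not per-value tiers).
- Tertile thresholds are relative: a country's tier depends on the
  reference cohort, so thresholds must be re-derived (or pinned in
  config) when the reference changes.
- Severity here is a between-country comparison aid, not an absolute
  needs estimate, and carries no funding formula.
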
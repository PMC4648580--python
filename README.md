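# cescore

Severity scoring of complex-emergency (CE) affected countries, built for
analysts and donors who need a transparent, numbers-based way to compare
levels of need across crises when allocating humanitarian funding.

## The model

A complex emergency is a manmade disaster in which civilian mortality from
direct or indirect conflict causes has risen significantly. Following the
Utstein-template logic, severity is a function of two components:

```
severity = f(V, E)
```

where **V** (vulnerability) captures a population's preexisting
susceptibility and **E** (exposure) the magnitude of the crisis impact.
Each component is proxied by four scored values:

| Component | Scored value | Units | Worse when |
|---|---|---|---|
| V | GNI per capita, PPP | current international $ | lower |
| V | Under-five mortality rate | per 1,000 live births | higher |
| V | Adult literacy rate | % ages 15+ | lower |
| V | Underweight prevalence | % of under-fives | higher |
| E | Persons affected | persons | higher |
| E | Persons affected | proportion of population | higher |
| E | Persons uprooted | persons | higher |
| E | Persons uprooted | proportion of population | higher |

Every value is placed in one of three tiers — **Low-Moderate** (1),
**High** (2), **Critical** (3) — relative to cut points derived as
tertiles of a reference distribution: vulnerability against ~50
low-development (HDI < 0.5) countries, exposure against appeal-scale
emergencies. Tier values sum to a component score (4–12), and the two
component scores combine — by sum (default, range 8–24) or product (range
16–144) — into one severity figure used to rank countries. Scoring
Low-Moderate does not indicate an acceptable situation, only that a
country scored less poorly than those scoring High or Critical.

Candidate indicators themselves are chosen by a three-criterion ranking
(evidence, timeliness, availability; 1–3 points each, 3–9 total) with a
field-diversity rule so no thematic sector dominates the selection.

## Worked example

Generate a synthetic cohort, derive thresholds, and score it end to end:

```
cescore run --n 8 --seed 7 --out demo.csv
```

which prints `end-to-end: scored 8 countries -> demo.csv`; the ranked
report (here summarised to its score columns) reads:

```
country  vulnerability_score  exposure_score  severity  complete
 CTY001                   11               8      19.0      True
 CTY007                   11               7      18.0      True
 CTY008                    6              10      16.0      True
 CTY003                    8               6      14.0      True
 CTY004                    8               6      14.0      True
 CTY005                    8               6      14.0      True
 CTY002                    7               6      13.0      True
 CTY006                    6               4      10.0      True
```

CTY001 ranks worst off: its eight tier values sum to 11 + 8 = 19 of a
possible 24. Ties (14.0) are broken by exposure score, then vulnerability
score, then name; countries with a fully missing component are listed
last with flags instead of a severity figure. The full report also
carries every raw value and its tier label per country.

The same pipeline runs stepwise on real data:

```
cescore rank-indicators --evidence evidence.csv --out ranked.csv
cescore derive-thresholds --reference ref.csv --exposure-reference caps.csv --out thresholds.json
cescore score --countries countries.csv --thresholds thresholds.json --out report.csv
```

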
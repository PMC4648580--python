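vulnerability_indicators:
- name: gni_per_capita
  label: GNI per capita, PPP
  category: vulnerability
  units: current international $
  polarity: higher_is_better
  field: economics
- name: u5mr
  label: Under-five mortality rate
  category: vulnerability
  units: per 1,000 live births
  polarity: higher_is_worse
  field: health
- name: adult_literacy
  label: Adult literacy rate
  category: vulnerability
  units: '% of people ages 15 and above'
  polarity: higher_is_better
  field: education
- name: underweight
  label: Underweight prevalence
  category: vulnerability
  units: '% of population under 5 years'
  polarity: higher_is_worse
  field: nutrition
exposure_indicators:
- name: affected
  label: Persons affected
  category: exposure
  units: persons
  polarity: higher_is_worse
  field: displacement
- name: uprooted
  label: Persons uprooted
  category: exposure
  units: persons
  polarity: higher_is_worse
  field: displacement
tier_labels:
- Low-Moderate
- High
- Critical
tier_values:
  Low-Moderate: 1
  High: 2
  Critical: 3
combiner: sum
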
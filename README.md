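# hiddenhunger

Composite country-level indices of **hidden hunger** — the chronic
deficiency of vitamins and minerals (iron, zinc, vitamin A, iodine)
that affects roughly two billion people without overt caloric hunger —
for public-health prioritization and advocacy.

The package builds two index families for every country with usable
data, plus the harmonization, association analyses and map/plot
outputs around them:

* **HHI-PD** (prevalence-based): the unweighted mean of stunting,
  iron-deficiency anemia (IDA) and vitamin A deficiency (VAD)
  prevalences (%) among preschool children,
  `HHI-PD = [stunting + IDA + low serum retinol] / 3`,
  on a 0–100 scale with severity bands mild [0, 20), moderate
  [20, 35), severe [35, 45), alarmingly high [45, 100].
* **HHI-DBa / HHI-DBu** (burden-based): disability-adjusted life
  years (DALYs) attributed to iron + zinc + vitamin A deficiency, per
  100,000 population (DBa) or as an absolute national total (DBu).

Harmonization applies the analysis rules before scoring: anemia →
IDA at 60 % (50 % in malaria-endemic settings); stunting as the zinc
proxy; VAD assumed absent where 2005 GDP/capita ≥ US$ 15,000 and no
retinol data exist; missing stunting imputed as the
population-weighted WHO-regional mean; countries with 2007 HDI ≥ 0.9
(or Life Expectancy Index when HDI is missing) excluded as highly
developed. Iodine deficiency is tracked and mapped but never enters
an index. Every value carries a provenance tag (`national_survey`,
`who_regression`, `regional_imputation`, `assumed_zero`, `missing`)
end to end.

A synthetic-data module generates country cohorts with the assumed
dependence structure (correlated stunting/anemia/VAD, decoupled
iodine, burden rising with prevalence, HDI falling with burden), so
the full pipeline is testable without any download. See
`docs/methods.md` for the model, parameters and limitations.

## Worked example

Generate the bundled fixture suite and score the 10-country worked
set:

```python
from hiddenhunger.synthetic import make_fixture_suite
make_fixture_suite("fx", seed=7)
```

```
$ hiddenhunger index --countries fx/worked10_countries.csv \
      --dalys fx/worked10_dalys.csv --out-dir out
HHI-PD for 7 countries; DALY indices for 5

$ head -5 out/index_table.csv
rank,iso3,name,who_region,stunting,ida,vad,hhi_pd,category,hhi_dba,hhi_dbu,pct_mnd_dalys,id_prevalence
1,WKD,Workd,AFR,60.0000,40.0000,50.0000,50.0000,alarmingly_high,4500.0000,1350000.0000,15.0000,
2,WKI,Worki,AFR,55.0000,35.0000,45.0000,45.0000,alarmingly_high,,,,
3,WKA,Worka,AFR,40.0000,36.0000,44.0000,40.0000,severe,5870.0000,5870.0000,1.0000,30.0000
4,WKB,Workb,SEAR,30.0000,25.0000,35.0000,30.0000,moderate,15.0000,150.0000,15.0000,10.0000

$ cat out/exclusions.csv
iso3,name,reason
WKE,Worke,hdi_at_or_above_threshold
WKF,Workf,lei_at_or_above_threshold
WKG,Workg,no_anemia_no_vad
```

Reading the top row: Workd's preschool stunting is 60 %, its anemia
(80 %, malaria-endemic) converts to 40 % IDA, VAD is 50 %, so
HHI-PD = (60+40+50)/3 = 50 — alarmingly high; its micronutrient DALY
rate is 4,500 per 100,000 (1.35 M DALYs at 30 M people, 15 % of its
all-cause burden). Worki's stunting (55 %) is the population-weighted
mean of its region's donors — its own survey value is missing — and
Worke/Workf/Workg fall to the three exclusion rules.

Association analysis on the study-scale synthetic stand-in tables:

```
$ hiddenhunger correlate --countries fx/appendix_s1_synthetic_countries.csv \
      --dalys fx/appendix_s1_synthetic_dalys.csv --out-dir out2
...
  hhi_pd hdi_2007 -1.000000 149
  hhi_pd  hhi_dba  0.889998 133
top-20 overlap (hhi_pd vs hhi_dba): 13
```

`simulate`, `harmonize`, `map` and `report-all` complete the CLI;
`report-all` writes the ranked table, the severity choropleth (from a
user-supplied GeoJSON with an `iso3` property) and the two
letter-glyph scatter plots (glyph = country initial, area ∝
population, color by region).

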
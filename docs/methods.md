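# Methods

## The indices

`hiddenhunger` scores the collective burden of micronutrient
deficiency ("hidden hunger") at the country level in two complementary
ways.

**Prevalence-based index (HHI-PD).** For preschool-age children
(0–4.99 y), the index is the unweighted mean of three national
prevalences, each on the 0–100 % scale:

    HHI-PD = [ stunting (%) + iron-deficiency anemia (%) + low serum retinol (%) ] / 3

Stunting (height-for-age z < −2 of the WHO growth standards) proxies
population zinc status; low serum/plasma retinol (< 0.70 µmol/L) is
vitamin A deficiency (VAD); iron-deficiency anemia (IDA) is derived
from total anemia with fixed attributable fractions (below). The score
ranges from 0 (best) to 100 (worst) and is banded into four severity
categories at full precision, half-open at the cut points:

| band | score |
|---|---|
| mild | [0, 20) |
| moderate | [20, 35) |
| severe | [35, 45) |
| alarmingly high | [45, 100] |

Iodine deficiency (urinary iodine < 100 µg/L in school-age children)
is carried through the pipeline and reported alongside, but never
averaged into any index: its geography is driven by salt-iodization
coverage and iodine sources rather than by the diet/infection etiology
the other three share, and it correlates only weakly with them.

**Burden-based indices (HHI-DBa, HHI-DBu).** From per-country DALY
(disability-adjusted life year) estimates attributed to iron, zinc and
vitamin A deficiency:

    HHI-DBa = iron + zinc + vitamin A DALYs per 100,000 population
    HHI-DBu = HHI-DBa × population / 100,000   (absolute DALYs)

Iodine-attributed DALYs are excluded for the same reasons as above and
because their coverage is incomplete. The upstream estimation of the
DALYs themselves (comparative risk assessment, PAFs, YLL/YLD) is out
of scope; DALY rates are inputs.

## Harmonization rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `ida_fraction_nonmalaria` | 0.60 | share of anemia attributed to iron deficiency outside malaria-endemic settings |
| `ida_fraction_malaria` | 0.50 | the same share where malaria is endemic (malaria inflates non-iron anemia) |
| `vad_free_gdp_threshold` | US$ 15,000 (2005 GDP per capita) | at or above this, a country with no retinol data is assumed VAD-free (prevalence 0, provenance `assumed_zero`) |
| `hdi_exclusion_threshold` | 0.9 | countries at or above this 2007 HDI (or Life Expectancy Index when HDI is missing) are excluded as highly developed |

Decisions where the rules leave room:

* **Boundaries.** HDI exactly 0.9 is excluded (inclusion is the strict
  rule, score < 0.9); GDP exactly 15,000 triggers the VAD-free
  assumption (closed bound). Raw scores are compared, not rounded
  ones.
* **Stunting imputation** is a single pass: a missing value gets the
  2009-population-weighted mean of *observed* stunting in the same WHO
  region; imputed values never serve as donors, so the result is
  independent of record order. A region with no donors leaves the
  value missing with a warning.
* **Missing population** is tolerated on read (warning, not error);
  operations that need it (HHI-DBu, the high-burden selection) report
  a missing result for that country instead of failing.
* **Exclusion reasons** are single-tag, first match wins:
  development score, then no-development-score, then
  no-anemia-and-no-VAD.
* **IDA in the index.** The malaria-adjusted IDA value is what enters
  HHI-PD by default; `ida_adjust=False` (CLI `--no-ida-adjust`) feeds
  raw anemia instead, as a sensitivity switch.
* **Malaria endemicity** is an input column, not a judgment made in
  code.
* **Correlations** use pairwise-complete deletion and always report
  the n used; no p-values are attached (rank correlations here are
  descriptive). `survey_only` restricts to national-survey provenance
  to show robustness against regression-based estimates.

The high-stunting-burden selection takes countries with stunting
≥ 20 %, orders them by estimated stunted children (prevalence ×
under-5 population), and cuts at the shortest prefix holding 90 % of
the *global* stunted-child total; the achieved coverage is returned
rather than forcing any particular list length.

## The synthetic cohort generator

No raw per-country survey compilation is bundled, so every stage is
exercised on synthetic cohorts with the dependence structure the
analysis assumes:

* **Gaussian copula with clamped linear marginal maps.** Latent
  normals with correlation 0.6 among (stunting, anemia, VAD) and 0.05
  with iodine deficiency are mapped to regional prevalence marginals
  (mean + sd·z, clipped to [0, 100]). Marginal sds are kept near
  mean/3.3 so clamping affects < 1 % of cells (the clamp fraction is
  returned in the truth record). The implied pairwise rank correlation
  of the copula is (6/π)·arcsin(ρ/2), which the recovery tests use as
  the target (±0.05 at n = 2,000).
* **Regional structure.** Region weights approximate the WHO-region
  country counts; regional prevalence means follow the broad
  gradients of the WHO micronutrient databases (highest in Africa and
  South-East Asia; iodine deficiency high in Europe and the Eastern
  Mediterranean, decoupled from the rest). Malaria endemicity is
  assigned by region (high probability in Africa/South-East Asia) so
  both IDA fractions are exercised. Note that the region mixture adds
  between-region correlation on top of the copula, so copula-level
  checks (identity bound, recovery) use a homogeneous-marginal spec.
* **Links.** Total micronutrient DALY rate = 40 per 100,000 per
  percentage point of mean deficiency burden, split 35/40/25 across
  iron/zinc/vitamin A with per-nutrient noise sd 130 and a floor at 0;
  this induces a prevalence–burden rank correlation around 0.9, the
  regime the real indices exhibit. HDI = 0.95 − 0.006·burden + noise
  (sd 0.05), so a realistic minority of (mostly low-burden) countries
  crosses the 0.9 exclusion threshold. Populations are log-normal
  (median ≈ 10 M, log-sd 1.3).
* **Missingness is completely at random** (per-field rates; iodine
  35 %, VAD 12 %, others ≤ 10 %). Real missingness is structural —
  surveys exist where programs and capacity exist — so passing tests
  on MCAR cohorts says nothing about bias from informative
  missingness. The generator also does not emulate survey microdata,
  within-country variation, or time trends.

Identical spec + seed gives byte-identical tables (fixed-order random
draws; fixed float formatting on write).

### The appendix-style stand-in

`synthetic_appendix()` is a deterministic, synthetic substitute for
the study-scale per-country tables: 190 prevalence-table countries (41
with development score ≥ 0.9, 149 included), a 136-country DALY table
sharing 133 countries with the included set, burden rates spanning
5,870 down to 15 per 100,000, a top-20 dominated by sub-Saharan Africa
plus India and Afghanistan, and a prevalence↔burden rank permutation
with Σd² = 43,130 over n = 133, i.e. Spearman ρ = 1 − 6Σd²/(n(n²−1)) ≈
0.8900 with a top-20 overlap of exactly 13. It exists to test the
pipeline's bookkeeping (counts, rankings, joins, extremes) at
realistic scale; its within-country component values are constructed,
not observed, and its internal component correlations are degenerate
by design — use `generate_cohort` for distributional realism.

## Numerical choices

* Scores are categorized at full precision; the "19.9 / 34.9 / 44.9"
  style of band labels reflects one-decimal reporting, not rounding
  before binning.
* Ranking ties are broken by iso3 ascending, so rankings are total and
  reproducible.
* Spearman correlations use average ranks for ties (scipy); results
  are flagged undefined below 3 complete pairs or for constant
  vectors.
* Percentages live on the 0–100 scale everywhere; only the policy
  fractions are proportions.
* SVG output pins the hash salt and strips the date so renders are
  byte-identical; glyph area (not diameter) scales with population,
  with a 4-point legibility floor.

## Test-suite problem sizes

Statistical property tests run at n = 2,000 countries (recovery,
marginal fidelity, prevalence–burden coupling) with derandomized
seeds; the identity-copula bound runs at n = 4,000 so the ±0.05 band
sits near 3.2 null standard errors instead of 2.2. Oracle checks use
200 small random tied vectors (Spearman) and 100 random region
configurations (imputation bounds).

## Known limitations

* IDA fractions (50/60 %) and the stunting-as-zinc proxy are
  assumptions carried from the analysis design, not estimated here.
* The pipeline scores only preschool children; pregnant women and
  other vulnerable groups are outside the indices.
* Prevalence and DALY inputs overlap in their underlying data, so the
  strong prevalence–burden correlation partially reflects shared
  inputs rather than independent confirmation.
* The choropleth expects user-supplied GeoJSON with an `iso3`
  property; no world boundaries are bundled, and no code-name
  reconciliation is attempted.
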
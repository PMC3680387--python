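"""Harmonization rules turning raw country indicator rows into an
analysis-ready panel.

The rules, applied in order by :func:`harmonize`:

1. High-income vitamin A assumption — countries with 2005 GDP per
   capita at or above US$15,000 and no retinol data are assumed free of
   vitamin A deficiency (prevalence 0, provenance ``assumed_zero``).
2. Regional stunting imputation — a missing stunting prevalence is
   replaced by the 2009-population-weighted mean of observed stunting
   in the same WHO region (single pass; imputed values never donate).
3. Development-based exclusion — countries whose effective development
   score (2007 HDI, or the Life Expectancy Index when HDI is missing)
   is at or above 0.9 are excluded, as are countries with neither
   anemia nor vitamin A data of any provenance.

Anemia is converted to iron-deficiency anemia (IDA) with fixed
attributable fractions: 60% outside malaria-endemic settings, 50%
within them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .records import ConversionPolicy, CountryRecord, PrevalenceEstimate, Provenance

logger = logging.getLogger(__name__)

__all__ = [
    "convert_anemia_to_ida",
    "ida_estimate",
    "assume_vad_free",
    "impute_stunting",
    "apply_exclusions",
    "harmonize",
]

# machine-readable exclusion reasons (first match wins)
REASON_HDI = "hdi_at_or_above_threshold"
REASON_LEI = "lei_at_or_above_threshold"
REASON_NO_SCORE = "no_development_score"
REASON_NO_DATA = "no_anemia_no_vad"


def convert_anemia_to_ida(
    anemia_prev: float,
    malaria_endemic: bool,
    policy: ConversionPolicy = ConversionPolicy(),
) -> float:
    """Anemia prevalence (%) -> iron-deficiency-anemia prevalence (%).

    Applies the fixed attributable fraction: ``ida_fraction_malaria``
    in malaria-endemic settings, ``ida_fraction_nonmalaria`` elsewhere.
    """
    if not 0.0 <= anemia_prev <= 100.0:
        raise ValueError(f"anemia prevalence {anemia_prev} outside [0, 100]")
    fraction = (
        policy.ida_fraction_malaria if malaria_endemic else policy.ida_fraction_nonmalaria
    )
    return anemia_prev * fraction


def ida_estimate(
    record: CountryRecord, policy: ConversionPolicy = ConversionPolicy()
) -> PrevalenceEstimate:
    """IDA estimate for a country; missing anemia stays missing
    (no default substitution), provenance is inherited."""
    if record.anemia.is_missing:
        return PrevalenceEstimate(None, record.anemia.age_group, Provenance.MISSING)
    return PrevalenceEstimate(
        convert_anemia_to_ida(record.anemia.value, record.malaria_endemic, policy),
        record.anemia.age_group,
        record.anemia.provenance,
    )


def assume_vad_free(
    record: CountryRecord, policy: ConversionPolicy = ConversionPolicy()
) -> CountryRecord:
    """Set VAD to 0 (``assumed_zero``) for high-income countries with
    no retinol data. Survey or regression values are never overwritten;
    no-op when GDP is missing."""
    if record.gdp_2005 is None:
        return record
    if record.gdp_2005 >= policy.vad_free_gdp_threshold and record.vad.is_missing:
        return record.with_field(
            vad=PrevalenceEstimate(0.0, record.vad.age_group, Provenance.ASSUMED_ZERO)
        )
    return record


def impute_stunting(records: Sequence[CountryRecord]) -> list[CountryRecord]:
    """Fill missing stunting with the 2009-population-weighted regional
    mean of observed values.

    Single pass: donors are only countries with observed (non-imputed)
    stunting and a 2009 population. A region with no donors leaves the
    value missing with a warning.
    """
    donors: dict[object, list[tuple[float, float]]] = {}
    for r in records:
        if not r.stunting.is_missing and r.population_2009 is not None:
            donors.setdefault(r.who_region, []).append(
                (r.stunting.value, r.population_2009)
            )

    out: list[CountryRecord] = []
    for r in records:
        if not r.stunting.is_missing:
            out.append(r)
            continue
        pool = donors.get(r.who_region, [])
        if not pool:
            logger.warning(
                "no stunting donors in region %s for %s; left missing",
                r.who_region.value, r.iso3,
            )
            out.append(r)
            continue
        total_pop = sum(p for _, p in pool)
        imputed = sum(v * p for v, p in pool) / total_pop
        out.append(
            r.with_field(
                stunting=PrevalenceEstimate(
                    imputed, r.stunting.age_group, Provenance.REGIONAL_IMPUTATION
                )
            )
        )
    return out


def apply_exclusions(
    records: Iterable[CountryRecord],
    policy: ConversionPolicy = ConversionPolicy(),
) -> tuple[list[CountryRecord], list[tuple[CountryRecord, str]]]:
    """Partition records into (included, excluded-with-reason).

    Exclusion rules, first match wins:

    * effective development score (HDI, else LEI) >= threshold — the
      highly-developed exclusion; exactly 0.9 is excluded;
    * neither score available — excluded with a warning, not an error;
    * both anemia and VAD missing (no survey and no regression value).
    """
    included: list[CountryRecord] = []
    excluded: list[tuple[CountryRecord, str]] = []
    thr = policy.hdi_exclusion_threshold
    for r in records:
        if r.hdi_2007 is not None and r.hdi_2007 >= thr:
            excluded.append((r, REASON_HDI))
        elif r.hdi_2007 is None and r.lei_2007 is not None and r.lei_2007 >= thr:
            excluded.append((r, REASON_LEI))
        elif r.development_score is None:
            logger.warning("%s has neither HDI nor LEI; excluded", r.iso3)
            excluded.append((r, REASON_NO_SCORE))
        elif r.anemia.is_missing and r.vad.is_missing:
            excluded.append((r, REASON_NO_DATA))
        else:
            included.append(r)
    return included, excluded


def harmonize(
    records: Sequence[CountryRecord],
    policy: ConversionPolicy = ConversionPolicy(),
) -> tuple[list[CountryRecord], list[tuple[CountryRecord, str]]]:
    """Full harmonization: VAD assumption, stunting imputation, then
    the inclusion/exclusion partition."""
    step1 = [assume_vad_free(r, policy) for r in records]
    step2 = impute_stunting(step1)
    return apply_exclusions(step2, policy)
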
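"""Domain records for country-level micronutrient deficiency data.

The pipeline's atom is :class:`CountryRecord` — one country's indicator
panel with per-field provenance — plus :class:`DalyRecord` for the
disease-burden side. Prevalences are carried on the 0–100 percentage
scale end to end; proportions appear only inside
:class:`ConversionPolicy`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Provenance",
    "AgeGroup",
    "WHORegion",
    "PrevalenceEstimate",
    "CountryRecord",
    "DalyRecord",
    "ConversionPolicy",
]


class Provenance(str, enum.Enum):
    """Where a prevalence estimate came from."""

    NATIONAL_SURVEY = "national_survey"
    WHO_REGRESSION = "who_regression"
    REGIONAL_IMPUTATION = "regional_imputation"
    ASSUMED_ZERO = "assumed_zero"
    MISSING = "missing"


class AgeGroup(str, enum.Enum):
    PRESCHOOL = "preschool"        # 0–4.99 years
    SCHOOL_AGE = "school_age"


class WHORegion(str, enum.Enum):
    AFR = "AFR"
    AMR = "AMR"
    SEAR = "SEAR"
    EUR = "EUR"
    EMR = "EMR"
    WPR = "WPR"


def _is_missing(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A national prevalence (%) with age group and provenance.

    Invariants: ``value`` is present iff ``provenance != MISSING``, and
    lies in [0, 100] when present.
    """

    value: Optional[float]
    age_group: AgeGroup = AgeGroup.PRESCHOOL
    provenance: Provenance = Provenance.MISSING

    def __post_init__(self) -> None:
        if self.is_missing:
            if self.provenance is not Provenance.MISSING:
                raise ValueError(
                    f"provenance {self.provenance.value!r} requires a value"
                )
            object.__setattr__(self, "value", None)
        else:
            if self.provenance is Provenance.MISSING:
                raise ValueError("a present value needs a non-missing provenance")
            if not 0.0 <= self.value <= 100.0:
                raise ValueError(f"prevalence {self.value} outside [0, 100]")

    @property
    def is_missing(self) -> bool:
        return _is_missing(self.value)

    @classmethod
    def missing(cls, age_group: AgeGroup = AgeGroup.PRESCHOOL) -> "PrevalenceEstimate":
        return cls(None, age_group, Provenance.MISSING)


MISSING_PREV = PrevalenceEstimate.missing()


@dataclass(frozen=True)
class CountryRecord:
    """One country's full indicator panel.

    ``stunting``, ``anemia`` and ``vad`` are prevalences among preschool
    children (0–4.99 y); ``id`` (iodine deficiency, urinary iodine
    < 100 µg/L) refers to school-age children. ``lei_2007`` is the Life
    Expectancy Index, the substitute development score when the 2007
    HDI is missing.
    """

    iso3: str
    name: str
    who_region: WHORegion
    ssa_member: bool = False
    hdi_2007: Optional[float] = None
    lei_2007: Optional[float] = None
    gdp_2005: Optional[float] = None
    population_2009: Optional[float] = None
    under5_population: Optional[float] = None
    malaria_endemic: bool = False
    stunting: PrevalenceEstimate = MISSING_PREV
    anemia: PrevalenceEstimate = MISSING_PREV
    vad: PrevalenceEstimate = MISSING_PREV
    id: PrevalenceEstimate = field(
        default=PrevalenceEstimate(None, AgeGroup.SCHOOL_AGE, Provenance.MISSING)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "iso3", self.iso3.strip().upper())
        for f in ("hdi_2007", "lei_2007"):
            v = getattr(self, f)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside the unit interval")
        if self.population_2009 is not None and not self.population_2009 > 0:
            raise ValueError(f"population_2009 must be > 0, got {self.population_2009}")
        if (
            self.under5_population is not None
            and self.population_2009 is not None
            and self.under5_population > self.population_2009
        ):
            raise ValueError("under5_population exceeds population_2009")

    @property
    def development_score(self) -> Optional[float]:
        """Effective development score: HDI, falling back to LEI."""
        return self.hdi_2007 if self.hdi_2007 is not None else self.lei_2007

    def with_field(self, **changes) -> "CountryRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class DalyRecord:
    """Micronutrient-attributed DALY rates for one country.

    Rates are DALYs per 100,000 population; ``total_all_cause_dalys``
    is an absolute count. Iodine DALYs are carried but never enter the
    burden indices.
    """

    iso3: str
    daly_iron: Optional[float] = None
    daly_zinc: Optional[float] = None
    daly_vita: Optional[float] = None
    daly_iodine: Optional[float] = None
    total_all_cause_dalys: Optional[float] = None
    population: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "iso3", self.iso3.strip().upper())
        for f in ("daly_iron", "daly_zinc", "daly_vita", "daly_iodine"):
            v = getattr(self, f)
            if v is not None and v < 0:
                raise ValueError(f"{f} must be >= 0, got {v}")


@dataclass(frozen=True)
class ConversionPolicy:
    """Fixed analysis assumptions for harmonization and inclusion.

    ``ida_fraction_*``: share of anemia attributed to iron deficiency
    (0.60 outside malaria-endemic settings, 0.50 within them).
    ``vad_free_gdp_threshold``: 2005 GDP per capita (US$) above which a
    country with no retinol data is assumed free of vitamin A
    deficiency. ``hdi_exclusion_threshold``: development score at or
    above which a country is excluded as highly developed.
    """

    ida_fraction_nonmalaria: float = 0.60
    ida_fraction_malaria: float = 0.50
    vad_free_gdp_threshold: float = 15_000.0
    hdi_exclusion_threshold: float = 0.9

    def __post_init__(self) -> None:
        for f in ("ida_fraction_nonmalaria", "ida_fraction_malaria"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be a proportion in [0, 1], got {v}")
        if not self.vad_free_gdp_threshold > 0:
            raise ValueError("vad_free_gdp_threshold must be positive")
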
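"""Hidden hunger indices.

Two families of composite country scores:

* **HHI-PD** — prevalence-based: the unweighted mean of stunting,
  iron-deficiency anemia and low-serum-retinol prevalences (%) among
  preschool children, on a 0–100 scale, banded into four severity
  categories (mild < 20 <= moderate < 35 <= severe < 45 <=
  alarmingly high).
* **HHI-DB** — burden-based: the sum of DALYs attributed to iron, zinc
  and vitamin A deficiency, either per 100,000 population (HHI-DBa) or
  as an absolute national total (HHI-DBu). Iodine-attributed DALYs are
  carried alongside but never enter either index.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .harmonize import ida_estimate
from .records import ConversionPolicy, CountryRecord, DalyRecord, WHORegion

__all__ = [
    "Severity",
    "CategoryScale",
    "HHIResult",
    "compute_hhi_pd",
    "categorize",
    "compute_hhi_dba",
    "compute_hhi_dbu",
    "percent_mnd_dalys",
    "rank_countries",
    "select_high_burden",
    "compute_prevalence_indices",
    "attach_daly_indices",
]


class Severity(str, enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    ALARMINGLY_HIGH = "alarmingly_high"


_SEVERITY_ORDER = list(Severity)


@dataclass(frozen=True)
class CategoryScale:
    """Severity cut points on the 0–100 score axis (half-open bands)."""

    boundaries: tuple[float, float, float] = (20.0, 35.0, 45.0)
    labels: tuple[Severity, Severity, Severity, Severity] = tuple(_SEVERITY_ORDER)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0.0 < b[0] < b[1] < b[2] < 100.0):
            raise ValueError(f"boundaries must be strictly increasing in (0,100): {b}")


@dataclass(frozen=True)
class HHIResult:
    """A country's index scores, severity category, and the component
    values actually averaged. Descriptive fields (name, region,
    population) ride along for ranking and plotting."""

    iso3: str
    hhi_pd: Optional[float] = None
    category: Optional[Severity] = None
    components: Optional[tuple[float, float, float]] = None  # (stunting, ida, vad)
    hhi_dba: Optional[float] = None
    hhi_dbu: Optional[float] = None
    pct_mnd_dalys: Optional[float] = None
    name: str = ""
    who_region: Optional[WHORegion] = None
    ssa_member: bool = False
    population: Optional[float] = None
    id_prevalence: Optional[float] = None  # reported alongside, never averaged in


def compute_hhi_pd(stunting: float, ida: float, vad: float) -> float:
    """Unweighted mean of the three component prevalences (%)."""
    for name, v in (("stunting", stunting), ("ida", ida), ("vad", vad)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name}={v} outside [0, 100]")
    return (stunting + ida + vad) / 3.0


def categorize(score: float, scale: CategoryScale = CategoryScale()) -> Severity:
    """Map a 0–100 score to its severity band.

    Bands are half-open at the cut points: [0,20) mild, [20,35)
    moderate, [35,45) severe, [45,100] alarmingly high. Scores are
    categorized at full precision.
    """
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"score {score} outside [0, 100]")
    for boundary, label in zip(scale.boundaries, scale.labels):
        if score < boundary:
            return label
    return scale.labels[-1]


def compute_hhi_dba(daly: DalyRecord) -> Optional[float]:
    """Sum of iron + zinc + vitamin A DALY rates (per 100,000).

    Iodine DALYs are never included. Any missing component makes the
    result missing.
    """
    parts = (daly.daly_iron, daly.daly_zinc, daly.daly_vita)
    if any(p is None for p in parts):
        return None
    return sum(parts)


def compute_hhi_dbu(daly: DalyRecord) -> Optional[float]:
    """Absolute hidden-hunger DALYs: rate sum scaled by population."""
    rate = compute_hhi_dba(daly)
    if rate is None or daly.population is None:
        return None
    return rate * daly.population / 100_000.0


def percent_mnd_dalys(daly: DalyRecord) -> Optional[float]:
    """Micronutrient-attributed DALYs as a % of all-cause DALYs."""
    absolute = compute_hhi_dbu(daly)
    if absolute is None or daly.total_all_cause_dalys is None:
        return None
    if not daly.total_all_cause_dalys > 0:
        raise ValueError("total_all_cause_dalys must be > 0")
    return 100.0 * absolute / daly.total_all_cause_dalys


_RANK_KEYS = {"hhi_pd", "hhi_dba", "hhi_dbu"}


def rank_countries(
    results: Iterable[HHIResult], key: str = "hhi_pd", descending: bool = True
) -> list[HHIResult]:
    """Order countries by an index, ties broken by iso3 ascending.

    Results with a missing key value are excluded from the ranking.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {sorted(_RANK_KEYS)}")
    scored = [r for r in results if getattr(r, key) is not None]
    sign = -1.0 if descending else 1.0
    return sorted(scored, key=lambda r: (sign * getattr(r, key), r.iso3))


def select_high_burden(
    records: Sequence[CountryRecord],
    stunting_floor: float = 20.0,
    coverage: float = 0.90,
) -> tuple[list[CountryRecord], float]:
    """High-stunting-burden selection.

    Candidates are countries with stunting prevalence >= ``stunting_floor``
    (%), ordered by their estimated number of stunted children
    (prevalence x under-5 population). The selection is the shortest
    prefix whose stunted-child total reaches ``coverage`` of the global
    stunted-child total (computed over all countries with data).
    Returns the selection and the coverage actually achieved.
    """

    def stunted(r: CountryRecord) -> Optional[float]:
        if r.stunting.is_missing or r.under5_population is None:
            return None
        return r.stunting.value / 100.0 * r.under5_population

    global_total = sum(s for r in records if (s := stunted(r)) is not None)
    candidates = []
    for r in records:
        if r.stunting.is_missing or r.stunting.value < stunting_floor:
            continue
        s = stunted(r)
        if s is None:
            import logging

            logging.getLogger(__name__).warning(
                "%s has stunting >= floor but no under-5 population; skipped", r.iso3
            )
            continue
        candidates.append((s, r))
    candidates.sort(key=lambda t: (-t[0], t[1].iso3))

    if global_total <= 0:
        return [], 0.0
    target = coverage * global_total
    selection: list[CountryRecord] = []
    cum = 0.0
    for s, r in candidates:
        if cum >= target:
            break
        selection.append(r)
        cum += s
    return selection, cum / global_total


def compute_prevalence_indices(
    included: Sequence[CountryRecord],
    policy: ConversionPolicy = ConversionPolicy(),
    scale: CategoryScale = CategoryScale(),
    ida_adjust: bool = True,
) -> list[HHIResult]:
    """HHI-PD for every included country with complete components.

    ``ida_adjust=False`` feeds raw anemia into the average instead of
    the malaria-adjusted IDA value. Countries missing any component get
    a result with ``hhi_pd=None`` (reported, not silently dropped).
    """
    out: list[HHIResult] = []
    for r in included:
        ida = r.anemia if not ida_adjust else ida_estimate(r, policy)
        base = dict(
            iso3=r.iso3,
            name=r.name,
            who_region=r.who_region,
            ssa_member=r.ssa_member,
            population=r.population_2009,
            id_prevalence=r.id.value,
        )
        if r.stunting.is_missing or ida.is_missing or r.vad.is_missing:
            out.append(HHIResult(**base))
            continue
        components = (r.stunting.value, ida.value, r.vad.value)
        score = compute_hhi_pd(*components)
        out.append(
            HHIResult(
                hhi_pd=score,
                category=categorize(score, scale),
                components=components,
                **base,
            )
        )
    return out


def attach_daly_indices(
    results: Sequence[HHIResult],
    dalys: Sequence[DalyRecord],
    country_lookup: Optional[Mapping[str, CountryRecord]] = None,
    policy: ConversionPolicy = ConversionPolicy(),
) -> list[HHIResult]:
    """Merge burden indices into (and extend) the prevalence results.

    Every eligible DALY-table country gets HHI-DBa / HHI-DBu and the
    micronutrient share of all-cause DALYs; countries absent from the
    prevalence results are appended with prevalence fields missing.
    Eligibility: a country whose record shows an effective development
    score at or above the exclusion threshold is dropped; countries
    with no record in ``country_lookup`` are kept (the DALY source is
    assumed to carry its own development screen).
    """
    by_iso = {r.iso3: r for r in results}
    merged = dict(by_iso)
    for d in dalys:
        if country_lookup is not None:
            rec = country_lookup.get(d.iso3)
            if rec is not None:
                score = rec.development_score
                if score is not None and score >= policy.hdi_exclusion_threshold:
                    continue
        dba = compute_hhi_dba(d)
        if dba is None:
            continue
        changes = dict(
            hhi_dba=dba,
            hhi_dbu=compute_hhi_dbu(d),
            pct_mnd_dalys=percent_mnd_dalys(d),
        )
        prev = merged.get(d.iso3)
        if prev is None:
            merged[d.iso3] = HHIResult(iso3=d.iso3, population=d.population, **changes)
        else:
            if prev.population is None:
                changes["population"] = d.population
            merged[d.iso3] = replace(prev, **changes)
    return sorted(merged.values(), key=lambda r: r.iso3)
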
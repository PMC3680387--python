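"""Rank-correlation and top-k overlap analyses.

All associations are Spearman rank correlations on pairwise-complete
observations (pairs with any missing value dropped; the n actually
used is always reported). No p-values are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import ida_estimate
from .indices import HHIResult
from .records import ConversionPolicy, CountryRecord, Provenance

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "pairwise_deficiency_correlations",
    "index_vs_covariate",
    "top_k_overlap",
]

MIN_PAIRS = 3


@dataclass(frozen=True)
class CorrelationResult:
    variable_x: str
    variable_y: str
    rho: Optional[float]  # None when undefined (n < 3 or zero variance)
    n: int

    @property
    def defined(self) -> bool:
        return self.rho is not None


def _clean_pairs(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    xa = np.array([math.nan if v is None else float(v) for v in x])
    ya = np.array([math.nan if v is None else float(v) for v in y])
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep]


def spearman_rho(
    x: Sequence, y: Sequence, variable_x: str = "x", variable_y: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling.

    Pairs with a missing value on either side are dropped first; the
    result is undefined (rho=None) below 3 complete pairs or when a
    vector is constant after cleaning.
    """
    xc, yc = _clean_pairs(x, y)
    n = len(xc)
    if n < MIN_PAIRS:
        return CorrelationResult(variable_x, variable_y, None, n)
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return CorrelationResult(variable_x, variable_y, None, n)
    rho = stats.spearmanr(xc, yc).statistic
    return CorrelationResult(variable_x, variable_y, float(rho), n)


_DEFICIENCY_FIELDS = ("stunting", "ida", "vad", "id")


def pairwise_deficiency_correlations(
    records: Sequence[CountryRecord],
    policy: ConversionPolicy = ConversionPolicy(),
    survey_only: bool = False,
) -> list[CorrelationResult]:
    """All pairwise Spearman correlations among stunting, IDA, VAD and
    iodine deficiency prevalences.

    ``survey_only`` restricts each variable to values with
    national-survey provenance (IDA inherits anemia's provenance) — the
    sensitivity analysis that screens out regression-based estimates.
    """

    def column(fieldname: str) -> list[Optional[float]]:
        vals: list[Optional[float]] = []
        for r in records:
            est = ida_estimate(r, policy) if fieldname == "ida" else getattr(r, fieldname)
            if est.is_missing:
                vals.append(None)
            elif survey_only and est.provenance is not Provenance.NATIONAL_SURVEY:
                vals.append(None)
            else:
                vals.append(est.value)
        return vals

    columns = {f: column(f) for f in _DEFICIENCY_FIELDS}
    out = []
    for i, fx in enumerate(_DEFICIENCY_FIELDS):
        for fy in _DEFICIENCY_FIELDS[i + 1 :]:
            out.append(spearman_rho(columns[fx], columns[fy], fx, fy))
    return out


def index_vs_covariate(
    results: Iterable[HHIResult],
    covariate: Mapping[str, Optional[float]],
    key: str = "hhi_pd",
    covariate_name: str = "covariate",
) -> CorrelationResult:
    """Spearman correlation between an index and a per-country
    covariate joined by iso3."""
    xs, ys = [], []
    for r in results:
        v = getattr(r, key)
        c = covariate.get(r.iso3)
        if v is not None and c is not None:
            xs.append(v)
            ys.append(c)
    return spearman_rho(xs, ys, key, covariate_name)


def top_k_overlap(rank_a: Sequence, rank_b: Sequence, k: int) -> int:
    """Size of the intersection of the two top-k sets.

    Accepts ordered lists of iso3 codes or of :class:`HHIResult`.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(rank_a) or k > len(rank_b):
        raise ValueError(f"k={k} exceeds a ranking's length ({len(rank_a)}, {len(rank_b)})")

    def ids(seq: Sequence) -> list[str]:
        return [r.iso3 if isinstance(r, HHIResult) else str(r) for r in seq[:k]]

    return len(set(ids(rank_a)) & set(ids(rank_b)))
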
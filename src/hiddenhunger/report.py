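"""Advocacy outputs: categorical choropleth maps, population-scaled
letter-glyph scatter plots, and the ranked index table.

Rendering never alters data — every plot is drawn from already-computed
:class:`~hiddenhunger.indices.HHIResult` values, and the per-category
polygon counts on a map reconcile exactly with the results table.
Outputs are deterministic: SVG hash salts are pinned and embedded
timestamps disabled, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.patches import Polygon as MplPolygon
from shapely.geometry import shape

from .association import spearman_rho
from .indices import HHIResult, Severity
from .records import WHORegion

logger = logging.getLogger(__name__)

__all__ = ["MapStyle", "render_choropleth", "render_letter_scatter", "write_ranked_table"]

# colorblind-safe sequential 4-step scheme (light -> dark)
_DEFAULT_PALETTE = ("#fee5d9", "#fcae91", "#fb6a4a", "#a50f15")

# approximate mapping of WHO regions onto the seven-group advocacy
# color scheme (Africa black, East Asia red, West/Central Asia yellow,
# Central/South America green, South Asia purple, Europe & high-income blue)
_REGION_COLORS = {
    WHORegion.AFR: "#000000",
    WHORegion.WPR: "#d62728",
    WHORegion.EMR: "#bfa700",
    WHORegion.AMR: "#2ca02c",
    WHORegion.SEAR: "#9467bd",
    WHORegion.EUR: "#1f77b4",
}


@dataclass(frozen=True)
class MapStyle:
    """Choropleth styling: one color per severity category plus
    visually distinct "no data" and "excluded" classes."""

    category_palette: tuple[str, str, str, str] = _DEFAULT_PALETTE
    no_data_color: str = "#d9d9d9"
    excluded_color: str = "#f0f0f0"
    edge_color: str = "#666666"
    join_key: str = "iso3"
    continuous_cmap: str = "YlOrRd"


def _pin_determinism() -> None:
    plt.rcParams["svg.hashsalt"] = "hiddenhunger"
    plt.rcParams["svg.fonttype"] = "none"


def _save(fig, out: str | Path) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, metadata={"Date": None} if out.suffix == ".svg" else None)
    plt.close(fig)
    return out


def _patches(geometry) -> list:
    geoms = geometry.geoms if geometry.geom_type.startswith("Multi") else [geometry]
    return [list(g.exterior.coords) for g in geoms]


def render_choropleth(
    results: Sequence[HHIResult],
    boundaries: dict | str | Path,
    style: MapStyle = MapStyle(),
    out: str | Path = "map.svg",
    value: str = "category",
    excluded: Iterable[str] = (),
    title: str = "",
) -> dict:
    """Fill a GeoJSON world by severity category (or a continuous ramp
    for a burden index) and write the figure.

    ``value``: "category" for the four-band severity fill, or
    "hhi_dba"/"hhi_dbu" for a continuous ramp. Countries listed in
    ``excluded`` are drawn in the excluded class. Returns a run log
    with per-class counts and the iso3 codes that failed to join.
    """
    if not isinstance(boundaries, dict):
        boundaries = json.loads(Path(boundaries).read_text())
    features = boundaries.get("features", [])
    by_iso = {r.iso3: r for r in results}
    excluded_set = {e.upper() for e in excluded}

    _pin_determinism()
    fig, ax = plt.subplots(figsize=(10, 5.5))
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)

    severities = list(Severity)
    vmax = None
    if value != "category":
        vals = [getattr(r, value) for r in results if getattr(r, value) is not None]
        if vals:
            vmax = max(vals) or 1.0
    cmap = plt.get_cmap(style.continuous_cmap)

    counts: dict[str, int] = {}
    matched: set[str] = set()
    joined = 0
    for feat in features:
        iso3 = str(feat.get("properties", {}).get(style.join_key, "")).upper()
        geom = shape(feat["geometry"])
        r = by_iso.get(iso3)
        if iso3 in excluded_set:
            color, klass = style.excluded_color, "excluded"
        elif r is None:
            color, klass = style.no_data_color, "no_data"
        elif value == "category":
            if r.category is None:
                color, klass = style.no_data_color, "no_data"
            else:
                color = style.category_palette[severities.index(r.category)]
                klass = r.category.value
        else:
            v = getattr(r, value)
            if v is None:
                color, klass = style.no_data_color, "no_data"
            else:
                color, klass = cmap(v / vmax), value
        if r is not None or iso3 in excluded_set:
            joined += 1
            matched.add(iso3)
        counts[klass] = counts.get(klass, 0) + 1
        for ring in _patches(geom):
            ax.add_patch(MplPolygon(ring, closed=True, facecolor=color,
                                    edgecolor=style.edge_color, linewidth=0.4))
    ax.autoscale_view()
    if joined == 0:
        plt.close(fig)
        raise ValueError("no result country matched any boundary feature")

    unmatched = sorted(set(by_iso) - matched)
    if unmatched:
        logger.warning("%d result countries not in boundaries: %s", len(unmatched), unmatched)
    _save(fig, out)
    return {"class_counts": counts, "unmatched": unmatched, "joined": joined}


def glyph_size(population: float, reference_population: float = 1e8, max_points: float = 28.0) -> float:
    """Font size for a country glyph: glyph *area* proportional to
    population, i.e. point size proportional to sqrt(population)."""
    if population is None or population <= 0:
        return 6.0
    return max(4.0, max_points * math.sqrt(population / reference_population))


def render_letter_scatter(
    results: Sequence[HHIResult],
    covariate: Mapping[str, Optional[float]],
    out: str | Path = "scatter.svg",
    key: str = "hhi_pd",
    covariate_name: str = "covariate",
    xlabel: str = "",
    ylabel: str = "",
) -> dict:
    """Scatter of an index against a covariate, each country drawn as
    the first letter of its name, sized by population and colored by
    region; the Spearman rho of the plotted pairs is printed in the
    margin. Returns a run log with the omitted (unjoined) countries."""
    _pin_determinism()
    fig, ax = plt.subplots(figsize=(8, 6))
    xs, ys = [], []
    omitted: list[str] = []
    plotted = 0
    for r in sorted(results, key=lambda r: r.iso3):
        v = getattr(r, key)
        c = covariate.get(r.iso3)
        if v is None or c is None:
            omitted.append(r.iso3)
            continue
        letter = (r.name or r.iso3)[0].upper()
        color = _REGION_COLORS.get(r.who_region, "#444444")
        ax.text(c, v, letter, fontsize=glyph_size(r.population), color=color,
                ha="center", va="center")
        xs.append(c)
        ys.append(v)
        plotted += 1
    if omitted:
        logger.warning("%d countries omitted from scatter (missing join): %s",
                       len(omitted), omitted)
    if xs:
        pad_x = (max(xs) - min(xs) or 1.0) * 0.06
        pad_y = (max(ys) - min(ys) or 1.0) * 0.06
        ax.set_xlim(min(xs) - pad_x, max(xs) + pad_x)
        ax.set_ylim(min(ys) - pad_y, max(ys) + pad_y)
    corr = spearman_rho(xs, ys, key, covariate_name)
    if corr.defined:
        ax.annotate(f"Spearman rho = {corr.rho:.2f} (n = {corr.n})",
                    xy=(0.02, 0.98), xycoords="axes fraction", va="top", fontsize=9)
    ax.set_xlabel(xlabel or covariate_name)
    ax.set_ylabel(ylabel or key)
    _save(fig, out)
    return {"plotted": plotted, "omitted": omitted,
            "rho": corr.rho if corr.defined else None, "n": corr.n}


def write_ranked_table(
    results: Sequence[HHIResult], path: str | Path, key: str = "hhi_pd", sep: str = ","
) -> pd.DataFrame:
    """Write the ranked index table (delimited text) and return it."""
    from .indices import rank_countries

    ranked = rank_countries(results, key=key)
    rows = []
    for rank, r in enumerate(ranked, start=1):
        comp = r.components or (None, None, None)
        rows.append(
            {
                "rank": rank,
                "iso3": r.iso3,
                "name": r.name,
                "who_region": r.who_region.value if r.who_region else "",
                "stunting": comp[0],
                "ida": comp[1],
                "vad": comp[2],
                "hhi_pd": r.hhi_pd,
                "category": r.category.value if r.category else "",
                "hhi_dba": r.hhi_dba,
                "hhi_dbu": r.hhi_dbu,
                "pct_mnd_dalys": r.pct_mnd_dalys,
                "id_prevalence": r.id_prevalence,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep=sep, index=False, float_format="%.4f")
    return df
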
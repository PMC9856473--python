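"""Slide-level density quantification and QC.

Operates on a lightweight synthetic representation of a stained slide — a
list of marker-positive cells with coordinates (mm) and staining intensities
(arbitrary units, AU), plus simple polygons delimiting the center of tumor
(CT) and the invasive margin (IM).  Densities are counts per polygon area in
cells/mm^2.  Slides are excluded when a region is missing or the mean
staining intensity of either marker is at or below the intensity gate
(default 152 AU).

Points exactly on a polygon boundary count as inside (closed regions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .reference import MARKER_REGION_PAIRS, MARKERS, REGIONS

#: Staining-intensity exclusion gate, in AU: slides with mean intensity <= this
#: value for either marker are excluded.
DEFAULT_INTENSITY_THRESHOLD = 152.0

QC_MISSING_REGION = "MISSING_REGION"
QC_LOW_INTENSITY = "LOW_INTENSITY"


@dataclass
class SyntheticSlide:
    """Synthetic stained slide: cell table + region polygons.

    ``cells`` columns: x, y (mm), marker ("CD3"/"CD8"), intensity (AU).
    ``regions`` maps region name to a simple shapely Polygon, or None when a
    region could not be delineated (MISSING).
    """

    cells: pd.DataFrame
    regions: Mapping[str, Optional[Polygon]]
    patient_id: str = ""

    def __post_init__(self):
        required = {"x", "y", "marker", "intensity"}
        if not required.issubset(self.cells.columns):
            raise ValueError(f"cell table must have columns {sorted(required)}")
        for col in ("x", "y", "intensity"):
            if not np.all(np.isfinite(self.cells[col].to_numpy(dtype=float))):
                raise ValueError(f"non-finite values in cell column {col!r}")
        for name, poly in self.regions.items():
            if poly is None:
                continue
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"region {name!r} polygon must be simple and valid")
            if poly.area <= 0:
                raise ValueError(f"region {name!r} polygon has non-positive area")


@dataclass
class SlideQuantification:
    """Per-patient densities (cells/mm^2 or NaN = missing) and QC outcome."""

    patient_id: str
    density: dict  # (marker, region) -> float, NaN when the region is missing
    mean_intensity: dict  # marker -> AU
    qc_pass: bool = False
    qc_reasons: list = field(default_factory=list)

    def __post_init__(self):
        for key, d in self.density.items():
            if not math.isnan(d) and d < 0:
                raise ValueError(f"density for {key} must be >= 0, got {d}")
        for m, v in self.mean_intensity.items():
            if v < 0:
                raise ValueError(f"mean intensity for {m} must be >= 0, got {v}")
        if self.qc_pass and self.qc_reasons:
            raise ValueError("qc_pass is true but qc_reasons is non-empty")


def region_density(slide: SyntheticSlide, marker: str, region: str) -> float:
    """Density of marker-positive cells inside a region polygon, cells/mm^2.

    Counts cells whose coordinates fall inside or on the boundary of the
    polygon, divided by the polygon area.  Returns NaN when the region
    polygon is missing.
    """
    poly = slide.regions.get(region)
    if poly is None:
        return float("nan")
    if poly.area <= 0:
        raise ValueError(f"region {region!r} has zero area")
    sub = slide.cells[slide.cells["marker"] == marker]
    if len(sub) == 0:
        return 0.0
    prepared = prep(poly)
    xs = sub["x"].to_numpy(dtype=float)
    ys = sub["y"].to_numpy(dtype=float)
    # covers() treats boundary points as inside (closed-region convention)
    inside = sum(1 for x, y in zip(xs, ys) if prepared.covers(Point(x, y)))
    return inside / poly.area


def quantify_slide(slide: SyntheticSlide) -> SlideQuantification:
    """Compute the four densities and per-marker mean intensities for a slide."""
    density = {
        (m, r): region_density(slide, m, r) for m, r in MARKER_REGION_PAIRS
    }
    mean_intensity = {}
    for m in MARKERS:
        sub = slide.cells[slide.cells["marker"] == m]
        mean_intensity[m] = float(sub["intensity"].mean()) if len(sub) else 0.0
    return SlideQuantification(
        patient_id=slide.patient_id, density=density, mean_intensity=mean_intensity
    )


def qc_slide(
    q: SlideQuantification, intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> SlideQuantification:
    """Apply the slide-level exclusion rules, returning ``q`` with QC populated.

    A slide fails QC when any of its four densities is missing
    (``MISSING_REGION``) or any marker's mean staining intensity is at or
    below ``intensity_threshold`` AU (``LOW_INTENSITY``).
    """
    if intensity_threshold < 0:
        raise ValueError("intensity threshold must be >= 0")
    reasons = []
    if any(math.isnan(q.density[key]) for key in MARKER_REGION_PAIRS):
        reasons.append(QC_MISSING_REGION)
    if any(q.mean_intensity.get(m, 0.0) <= intensity_threshold for m in MARKERS):
        reasons.append(QC_LOW_INTENSITY)
    return SlideQuantification(
        patient_id=q.patient_id,
        density=dict(q.density),
        mean_intensity=dict(q.mean_intensity),
        qc_pass=not reasons,
        qc_reasons=reasons,
    )


def default_slide_geometry(
    area_ct: float = 4.0, area_im: float = 4.0, gap: float = 0.5
) -> dict[str, Polygon]:
    """Two disjoint square regions (CT left, IM right) with the given areas (mm^2)."""
    s_ct = math.sqrt(area_ct)
    s_im = math.sqrt(area_im)
    ct = Polygon([(0, 0), (s_ct, 0), (s_ct, s_ct), (0, s_ct)])
    x0 = s_ct + gap
    im = Polygon([(x0, 0), (x0 + s_im, 0), (x0 + s_im, s_im), (x0, s_im)])
    return {"CT": ct, "IM": im}


def write_slide(slide: SyntheticSlide, cells_path, regions_path) -> None:
    """Serialize a slide as a cell table (x, y, marker, intensity) plus a
    region-polygon table (region, vertex index, x, y), both CSV."""
    slide.cells.to_csv(cells_path, index=False, float_format="%.10g")
    rows = []
    for name, poly in slide.regions.items():
        if poly is None:
            continue
        for i, (x, y) in enumerate(poly.exterior.coords[:-1]):
            rows.append((name, i, x, y))
    pd.DataFrame(rows, columns=["region", "vertex", "x", "y"]).to_csv(
        regions_path, index=False, float_format="%.10g")


def read_slide(cells_path, regions_path, patient_id: str = "") -> SyntheticSlide:
    """Inverse of :func:`write_slide`; regions absent from the file are MISSING."""
    cells = pd.read_csv(cells_path)
    poly_df = pd.read_csv(regions_path)
    regions: dict[str, Optional[Polygon]] = {r: None for r in REGIONS}
    for name, grp in poly_df.groupby("region"):
        grp = grp.sort_values("vertex")
        regions[name] = Polygon(list(zip(grp["x"], grp["y"])))
    return SyntheticSlide(cells=cells, regions=regions, patient_id=patient_id)


def _uniform_points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator):
    """Rejection-sample n uniform points inside (or on) a polygon."""
    minx, miny, maxx, maxy = poly.bounds
    prepared = prep(poly)
    xs, ys = [], []
    while len(xs) < n:
        m = max(32, int(1.5 * (n - len(xs)) * (maxx - minx) * (maxy - miny) / poly.area))
        cx = rng.uniform(minx, maxx, size=m)
        cy = rng.uniform(miny, maxy, size=m)
        for x, y in zip(cx, cy):
            if prepared.covers(Point(x, y)):
                xs.append(x)
                ys.append(y)
                if len(xs) == n:
                    break
    return np.array(xs), np.array(ys)


def simulate_slide(
    target_densities: Mapping[tuple[str, str], float],
    intensity_spec: Mapping[str, tuple[float, float]] | None = None,
    *,
    regions: Mapping[str, Optional[Polygon]] | None = None,
    seed: int,
    patient_id: str = "",
) -> SyntheticSlide:
    """Simulate a stained slide as homogeneous Poisson point patterns.

    For each (marker, region) a Poisson number of cells with mean
    ``target_density x region area`` is placed uniformly in the region
    polygon.  Per-cell intensities are drawn Normal(mean, sd) per marker,
    truncated at 0 (``intensity_spec``; default mean 200 AU, sd 15).
    Deterministic given ``seed``.
    """
    if intensity_spec is None:
        intensity_spec = {m: (200.0, 15.0) for m in MARKERS}
    if regions is None:
        regions = default_slide_geometry()
    rng = np.random.default_rng(seed)
    rows = []
    for marker in MARKERS:
        mu, sd = intensity_spec[marker]
        for region in REGIONS:
            target = float(target_densities.get((marker, region), 0.0))
            if target < 0:
                raise ValueError(f"target density for ({marker}, {region}) must be >= 0")
            poly = regions.get(region)
            if poly is None or target == 0.0:
                continue
            n = int(rng.poisson(target * poly.area))
            if n == 0:
                continue
            xs, ys = _uniform_points_in_polygon(poly, n, rng)
            intens = np.clip(rng.normal(mu, sd, size=n), 0.0, None)
            for x, y, a in zip(xs, ys, intens):
                rows.append((x, y, marker, a))
    cells = pd.DataFrame(rows, columns=["x", "y", "marker", "intensity"])
    if cells.empty:
        cells = pd.DataFrame(
            {"x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
             "marker": pd.Series(dtype=object), "intensity": pd.Series(dtype=float)}
        )
    return SyntheticSlide(cells=cells, regions=dict(regions), patient_id=patient_id)
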
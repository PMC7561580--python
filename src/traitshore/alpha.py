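"""Alpha functional diversity: convex-hull richness and dispersion.

Functional richness (FRic) is the volume of the convex hull spanned by a
community's species in the retained ordination axes, scaled to the hull
of the whole species pool so values benchmark against the potential
maximum. Functional dispersion (FDis) is the abundance-weighted mean
distance of species to their abundance-weighted centroid. Both are
computed at the quadrat (small) and zone (large) scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .containers import (
    ZONE_INDICATORS,
    ZONES,
    CommunityMatrix,
    ValidationError,
)
from .groups import EmergentGrouping
from .trait_space import FunctionalSpace

log = logging.getLogger(__name__)


@dataclass
class AlphaRecord:
    unit: str
    scale: str                 # "quadrat" | "zone"
    species_richness: int
    group_richness: int | None
    fric_raw: float            # hull volume (nan when S < 3)
    fric_scaled: float         # community / pool hull volume, in [0,1]
    fdis: float
    degenerate: bool = False


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume; in 1D the segment length. Raises QhullError
    for affinely dependent point sets in >= 2D."""
    pts = np.asarray(points, float)
    if pts.ndim != 2:
        raise ValidationError("points must be 2-D (n x m)")
    if pts.shape[1] == 1:
        return float(pts.max() - pts.min())
    return float(ConvexHull(pts).volume)


def hull_volume_reduced(pts: np.ndarray, m_cap: int | None = None) -> tuple:
    """(volume, dimensions used) with the low-richness reduction.

    Starts from min(m, S-1) axes and keeps dropping the last axis while
    the point set is affinely dependent (e.g. collinear points in 2D
    reduce to the 1D span). Identical points yield volume 0 in 1D.
    """
    pts = np.asarray(pts, float)
    S, m = pts.shape
    m_eff = min(m if m_cap is None else m_cap, S - 1)
    while m_eff > 1:
        try:
            return hull_volume(pts[:, :m_eff]), m_eff
        except QhullError:
            m_eff -= 1
    return hull_volume(pts[:, :1]), 1


def functional_richness(coords_present: np.ndarray,
                        pool_coords: np.ndarray) -> tuple:
    """(fric_raw, fric_scaled, degenerate_flag) for one community.

    When richness S <= m the hull is degenerate in m axes, so both the
    community and the pool are re-embedded in the first S-1 axes and the
    flag is set; affinely dependent point sets (e.g. collinear) keep
    reducing until a full-dimensional hull exists. Fewer than 3 species
    leaves FRic undefined (nan).
    """
    pts = np.asarray(coords_present, float)
    pool = np.asarray(pool_coords, float)
    S, m = pts.shape
    if S < 3:
        return np.nan, np.nan, True
    vol, m_used = hull_volume_reduced(pts)
    degenerate = m_used < m
    if degenerate and m_used < min(m, S - 1):
        warnings.warn("affinely dependent community points; hull "
                      f"computed in {m_used} axes")
    pool_vol, _ = hull_volume_reduced(pool, m_cap=m_used)
    if pool_vol == 0:
        return float(vol), np.nan, True
    scaled = vol / pool_vol
    if scaled > 1.0:
        if scaled > 1.0 + 1e-6:
            warnings.warn(f"scaled FRic {scaled:.6f} > 1; clipping")
        scaled = 1.0
    return float(vol), float(scaled), degenerate


def functional_dispersion(coords_present: np.ndarray,
                          abundances: np.ndarray) -> float:
    """Abundance-weighted mean distance to the weighted centroid.

    c = sum(a_j x_j)/sum(a_j); FDis = sum(a_j ||x_j - c||)/sum(a_j).
    Invariant to rescaling abundances; a single species gives 0.
    """
    pts = np.asarray(coords_present, float)
    a = np.asarray(abundances, float)
    if (a < 0).any():
        raise ValidationError("abundances must be >= 0")
    if a.sum() <= 0:
        raise ValidationError("at least one abundance must be positive")
    w = a / a.sum()
    c = w @ pts
    return float(w @ np.linalg.norm(pts - c, axis=1))


def indicator_species() -> list:
    return [s for pair in ZONE_INDICATORS.values() for s in pair]


def alpha_table(cm: CommunityMatrix, fs: FunctionalSpace,
                grouping: EmergentGrouping | None = None,
                exclude_indicators: bool = False) -> pd.DataFrame:
    """AlphaRecords at quadrat and zone scale as a tidy table.

    Zone-scale presence pools all quadrats of the zone; zone abundances
    are summed cover. ``exclude_indicators`` drops the six zone-defining
    fucoids/kelp first (sensitivity re-analysis).
    """
    if exclude_indicators:
        cm = cm.drop_species([s for s in indicator_species()
                              if s in cm.species_ids])
    gvec = (grouping.assignment.reindex(cm.species_ids).to_numpy()
            if grouping is not None else None)
    if gvec is not None and pd.isna(gvec).any():
        bad = [s for s, g in zip(cm.species_ids, gvec) if pd.isna(g)]
        raise ValidationError(f"species not in grouping: {bad}")
    coords = fs.coords_for(cm.species_ids)
    pool = fs.coordinates

    records = []

    def one(unit, scale, cover_row):
        mask = cover_row > 0
        S = int(mask.sum())
        g = (len(set(gvec[mask])) if gvec is not None and S else
             (0 if gvec is not None else None))
        if S == 0:
            records.append(AlphaRecord(unit, scale, 0, g, np.nan, np.nan,
                                       np.nan, True))
            return
        fr, fs_, deg = functional_richness(coords[mask], pool)
        fd = functional_dispersion(coords[mask], cover_row[mask])
        records.append(AlphaRecord(unit, scale, S, g, fr, fs_, fd, deg))

    arr = cm.cover.to_numpy(float)
    for i, qid in enumerate(cm.quadrat_ids):
        one(qid, "quadrat", arr[i])
    zone_cover = cm.zone_cover()
    if zone_cover.isna().all(axis=1).any() or len(zone_cover) == 0:
        raise ValidationError("a zone has no quadrats")
    for z in zone_cover.index:
        one(z, "zone", zone_cover.loc[z].to_numpy(float))

    df = pd.DataFrame([r.__dict__ for r in records])
    return df


def zone_summary(alpha: pd.DataFrame) -> pd.DataFrame:
    """Zone-scale rows of an alpha table, ordered low -> upper."""
    z = alpha[alpha["scale"] == "zone"].set_index("unit")
    return z.reindex([zz for zz in ZONES if zz in z.index])
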
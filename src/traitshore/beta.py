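"""Multiple-site beta diversity partitioned into turnover and nestedness.

Taxonomic beta uses the Baselga multiple-site Sorensen family on species
incidences; functional beta replaces species counts by convex-hull
volumes, with shared volume given by polytope intersection (exact
half-space intersection up to 3 axes, seeded Monte Carlo above). Both
partition total dissimilarity (beta_SOR) into a turnover component
(beta_SIM) and a nestedness-resultant component (beta_SNE = SOR - SIM).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .containers import CommunityMatrix, ValidationError
from .trait_space import FunctionalSpace

log = logging.getLogger(__name__)


@dataclass
class BetaPartition:
    level: str                     # "taxonomic" | "functional"
    beta_sor: float
    beta_sim: float
    beta_sne: float
    site_set: str = ""

    def __post_init__(self):
        if self.beta_sim > self.beta_sor + 1e-9:
            raise ValidationError("turnover exceeds total dissimilarity")

    @property
    def nestedness_share(self) -> float:
        return self.beta_sne / self.beta_sor if self.beta_sor > 0 else np.nan

    def as_dict(self) -> dict:
        return {"level": self.level, "site_set": self.site_set,
                "beta_sor": self.beta_sor, "beta_sim": self.beta_sim,
                "beta_sne": self.beta_sne,
                "nestedness_share": self.nestedness_share}


# ---------------------------------------------------------------------------
# taxonomic (incidence-based) partition

def beta_taxonomic(presence_by_site: dict, site_set: str = "") -> BetaPartition:
    """Baselga multiple-site Sorensen partition on incidences.

    With b_ij, b_ji the species exclusive to each site of a pair,
    beta_SIM = sum(min) / (sum_i S_i - S_T + sum(min)) and
    beta_SOR = (sum(min)+sum(max)) / (2(sum_i S_i - S_T)+sum(min)+sum(max)).
    """
    sets = {k: set(v) for k, v in presence_by_site.items()}
    if len(sets) < 2:
        raise ValidationError("need >= 2 assemblages")
    for k, s in sets.items():
        if not s:
            raise ValidationError(f"assemblage {k!r} is empty")
    names = list(sets)
    sum_min = sum_max = 0.0
    for a, b in itertools.combinations(names, 2):
        b_ab = len(sets[a] - sets[b])
        b_ba = len(sets[b] - sets[a])
        sum_min += min(b_ab, b_ba)
        sum_max += max(b_ab, b_ba)
    total = len(set.union(*sets.values()))
    shared_excess = sum(len(s) for s in sets.values()) - total
    if sum_min + sum_max == 0:
        return BetaPartition("taxonomic", 0.0, 0.0, 0.0, site_set)
    sor = (sum_min + sum_max) / (2 * shared_excess + sum_min + sum_max)
    sim = sum_min / (shared_excess + sum_min) if (shared_excess + sum_min) \
        else 0.0
    return BetaPartition("taxonomic", float(sor), float(sim),
                         float(sor - sim), site_set)


# ---------------------------------------------------------------------------
# polytope intersection

def _halfspaces(points: np.ndarray) -> np.ndarray:
    """Qhull half-space system A x + b <= 0 of a point cloud's hull."""
    return ConvexHull(points).equations


def _chebyshev_center(halfspaces: np.ndarray):
    """Centre and radius of the largest inscribed ball (LP)."""
    A, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    m = A.shape[1]
    res = linprog(c=np.r_[np.zeros(m), -1.0],
                  A_ub=np.hstack([A, norms]), b_ub=-b,
                  bounds=[(None, None)] * m + [(0, None)],
                  method="highs")
    if not res.success:
        return None, -np.inf
    return res.x[:m], res.x[m]


def hull_intersection_volume(coords_a: np.ndarray, coords_b: np.ndarray,
                             exact: bool | None = None,
                             mc_draws: int = 100_000,
                             rng_seed: int = 0) -> float:
    """Volume of the intersection of two convex hulls.

    Exact route (default for <= 3 axes): pool both half-space systems,
    locate an interior point by Chebyshev-centre LP, enumerate vertices
    with scipy's HalfspaceIntersection, and take their hull volume. An
    empty or lower-dimensional intersection gives 0. Monte Carlo route
    (default for >= 4 axes, or fallback): rejection sampling in the
    intersection of bounding boxes.
    """
    return _intersection_volume_multi([coords_a, coords_b], exact=exact,
                                      mc_draws=mc_draws, rng_seed=rng_seed)


def _intersection_volume_multi(coord_sets, exact=None, mc_draws=100_000,
                               rng_seed=0) -> float:
    coord_sets = [np.asarray(c, float) for c in coord_sets]
    m = coord_sets[0].shape[1]
    if any(c.shape[1] != m for c in coord_sets):
        raise ValidationError("all hulls must share dimensionality")
    for c in coord_sets:
        if len(c) < m + 1:
            raise ValidationError(
                "degenerate hull: fewer points than axes + 1")
    if exact is None:
        exact = m <= 3
    try:
        hs = np.vstack([_halfspaces(c) for c in coord_sets])
    except QhullError as err:
        raise ValidationError(f"degenerate hull: {err}") from err
    if exact:
        centre, radius = _chebyshev_center(hs)
        if centre is None or radius <= 1e-12:
            return 0.0
        try:
            inter = HalfspaceIntersection(hs, centre)
            verts = inter.intersections
            if len(verts) < m + 1:
                return 0.0
            return float(ConvexHull(verts).volume)
        except QhullError:
            log.warning("vertex enumeration failed; Monte Carlo fallback")
    # Monte Carlo: sample in the overlap of axis-aligned bounding boxes
    lo = np.max([c.min(axis=0) for c in coord_sets], axis=0)
    hi = np.min([c.max(axis=0) for c in coord_sets], axis=0)
    if (hi <= lo).any():
        return 0.0
    rng = np.random.default_rng(rng_seed)
    pts = rng.uniform(lo, hi, size=(mc_draws, m))
    inside = np.ones(mc_draws, bool)
    for c in coord_sets:
        eq = _halfspaces(c)
        inside &= (pts @ eq[:, :-1].T + eq[:, -1] <= 1e-9).all(axis=1)
    box_vol = float(np.prod(hi - lo))
    return box_vol * inside.mean()


# ---------------------------------------------------------------------------
# functional (hull-volume) partition

def beta_functional(coords_by_site: dict, exact: bool | None = None,
                    mc_draws: int = 100_000, rng_seed: int = 0,
                    site_set: str = "") -> BetaPartition:
    """Multiple-site functional Sorensen partition.

    Species counts of the taxonomic formulas are replaced by hull
    volumes: exclusive fractions come from pairwise intersections, and
    the union volume (for the shared term) from inclusion-exclusion over
    pairwise and higher-order hull intersections.
    """
    names = list(coords_by_site)
    if len(names) < 2:
        raise ValidationError("need >= 2 assemblages")
    coords = {k: np.asarray(v, float) for k, v in coords_by_site.items()}
    m = next(iter(coords.values())).shape[1]
    min_pts = min(len(c) for c in coords.values())
    if min_pts <= m:
        m = min_pts - 1
        if m < 1:
            raise ValidationError("an assemblage has too few species "
                                  "for any hull")
        log.warning("reducing functional beta to %d axes (smallest "
                    "assemblage limits hull dimensionality)", m)
        coords = {k: v[:, :m] for k, v in coords.items()}
        if exact is None:
            exact = m <= 3

    from .alpha import hull_volume
    vol = {k: hull_volume(c) for k, c in coords.items()}
    inter = {}
    combo_id = 0
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            combo_id += 1
            inter[combo] = _intersection_volume_multi(
                [coords[k] for k in combo], exact=exact,
                mc_draws=mc_draws, rng_seed=rng_seed + combo_id)
    union = sum(vol.values())
    for combo, v in inter.items():
        union += ((-1) ** (len(combo) - 1)) * v

    sum_min = sum_max = 0.0
    for a, b in itertools.combinations(names, 2):
        ab = inter[(a, b)] if (a, b) in inter else inter[(b, a)]
        b_ab = max(vol[a] - ab, 0.0)
        b_ba = max(vol[b] - ab, 0.0)
        sum_min += min(b_ab, b_ba)
        sum_max += max(b_ab, b_ba)
    shared_excess = max(sum(vol.values()) - union, 0.0)
    if sum_min + sum_max <= 0:
        return BetaPartition("functional", 0.0, 0.0, 0.0, site_set)
    sor = (sum_min + sum_max) / (2 * shared_excess + sum_min + sum_max)
    sim = sum_min / (shared_excess + sum_min) if (shared_excess + sum_min) \
        else 0.0
    sim = min(sim, sor)
    return BetaPartition("functional", float(sor), float(sim),
                         float(sor - sim), site_set)


# ---------------------------------------------------------------------------
# zone-level report

def beta_report(cm: CommunityMatrix, fs: FunctionalSpace,
                mc_draws: int = 100_000, rng_seed: int = 0) -> pd.DataFrame:
    """Taxonomic and functional partitions across zones: all quadrats,
    rock-pool-present only, and rock-pool-absent only."""
    rows = []
    rp = cm.rockpool_present
    subsets = {"all": cm.quadrat_ids,
               "rockpool_present": [q for q in cm.quadrat_ids if rp[q]],
               "rockpool_absent": [q for q in cm.quadrat_ids if not rp[q]]}
    for name, quadrats in subsets.items():
        if not quadrats:
            warnings.warn(f"habitat subset {name!r} empty; skipped")
            continue
        sub = cm.subset(quadrats)
        zp = sub.zone_presence()
        if len(zp) < 2:
            warnings.warn(f"subset {name!r} spans < 2 zones; skipped")
            continue
        pres = {z: set(zp.columns[zp.loc[z]]) for z in zp.index}
        rows.append(beta_taxonomic(pres, site_set=name).as_dict())
        coords = {z: fs.coords_for(sorted(sp)) for z, sp in pres.items()}
        rows.append(beta_functional(coords, mc_draws=mc_draws,
                                    rng_seed=rng_seed,
                                    site_set=name).as_dict())
    return pd.DataFrame(rows)
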
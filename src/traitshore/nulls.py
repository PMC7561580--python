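"""Trait-shuffling null models and standardized effect sizes.

Null communities keep each quadrat's species richness and abundance
structure fixed and shuffle species' positions on the trait matrix.
Shuffling trait rows is exactly a relabelling of points in the fixed
pool-level ordination, so the functional space is built once and nulls
only permute the species -> coordinate mapping (999 replicates by
default). The standardized effect size SES = (obs - null mean)/null sd
is negative when a community occupies less trait space than random
draws of equal richness (environmental filtering) and positive when it
is over-dispersed (limiting similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alpha import functional_dispersion, hull_volume_reduced
from .containers import CommunityMatrix, ValidationError
from .trait_space import FunctionalSpace

log = logging.getLogger(__name__)

METRICS = ("fric", "fdis")


@dataclass
class SESRecord:
    quadrat: str
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_null: int
    constrained: str = "none"      # "none" | "within_zone"
    defined: bool = True


def shuffle_traits(n_species: int, rng: np.random.Generator,
                   pool: np.ndarray | None = None) -> np.ndarray:
    """One null relabelling: a permutation of species indices.

    With a restricted ``pool`` (zone-constrained variant) only the pool
    members are permuted among themselves; everything else maps to
    itself. The mapping is a bijection, so the multiset of trait rows —
    and hence the overall functional structure — is conserved.
    """
    perm = np.arange(n_species)
    if pool is None:
        return rng.permutation(n_species)
    pool = np.asarray(pool, int)
    if len(pool) < 2:
        raise ValidationError("shuffle pool must have >= 2 species")
    perm[pool] = pool[rng.permutation(len(pool))]
    return perm


def _fric_raw(pts: np.ndarray) -> float:
    """Hull volume with the low-richness dimensionality reduction
    (S <= m -> first S-1 axes); nan below 3 species."""
    if len(pts) < 3:
        return np.nan
    return hull_volume_reduced(pts)[0]


def ses(cm: CommunityMatrix, fs: FunctionalSpace, metric: str,
        n_null: int = 999, constraint: str = "none",
        rng_seed: int = 0) -> pd.DataFrame:
    """Per-quadrat SES of functional richness or dispersion.

    Each of the ``n_null`` replicates draws one independent permutation
    of the species pool (or one per zone under the ``within_zone``
    constraint, where the pool is the set of species recorded anywhere
    in that zone) and re-evaluates the metric for every quadrat under
    the permuted species -> coordinate mapping. FRic needs >= 3 species;
    quadrats below that, or with a null sd of zero, are flagged
    undefined and excluded from downstream tests.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}")
    if constraint not in ("none", "within_zone"):
        raise ValidationError(f"unknown constraint {constraint!r}")
    rng = np.random.default_rng(rng_seed)
    X = fs.coords_for(cm.species_ids)          # pool coordinates
    n_sp = len(cm.species_ids)
    cover = cm.cover.to_numpy(float)
    present = [np.flatnonzero(cover[i] > 0) for i in range(len(cover))]
    abund = [cover[i][p] for i, p in enumerate(present)]

    zone_pools = None
    quadrat_zone = None
    if constraint == "within_zone":
        zp = cm.zone_presence()
        zone_pools = {z: np.flatnonzero(zp.loc[z].to_numpy())
                      for z in zp.index}
        quadrat_zone = cm.zone.to_numpy()

    def evaluate(idx, a, mapping):
        pts = X[mapping[idx]]
        if metric == "fric":
            return _fric_raw(pts)
        return functional_dispersion(pts, a) if len(idx) else np.nan

    identity = np.arange(n_sp)
    observed = np.array([evaluate(p, a, identity)
                         for p, a in zip(present, abund)])

    nulls = np.empty((n_null, len(present)))
    for r in range(n_null):
        if constraint == "none":
            mapping = shuffle_traits(n_sp, rng)
            maps = None
        else:
            maps = {z: shuffle_traits(n_sp, rng, pool)
                    for z, pool in zone_pools.items()}
            mapping = None
        for i, (p, a) in enumerate(zip(present, abund)):
            mp = mapping if maps is None else maps[quadrat_zone[i]]
            nulls[r, i] = evaluate(p, a, mp)

    records = []
    for i, qid in enumerate(cm.quadrat_ids):
        col = nulls[:, i]
        obs = observed[i]
        if np.isnan(obs) or np.isnan(col).any():
            records.append(SESRecord(qid, metric, obs, np.nan, np.nan,
                                     np.nan, n_null, constraint, False))
            continue
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0:
            records.append(SESRecord(qid, metric, obs, mu, 0.0, np.nan,
                                     n_null, constraint, False))
            continue
        records.append(SESRecord(qid, metric, float(obs), mu, sd,
                                 (float(obs) - mu) / sd, n_null,
                                 constraint, True))
    n_undef = sum(not r.defined for r in records)
    if n_undef:
        log.info("%d quadrats with undefined SES (%s, %s)", n_undef,
                 metric, constraint)
    return pd.DataFrame([r.__dict__ for r in records])


def test_ses(ses_values, alpha_normality: float = 0.05) -> dict:
    """One-sample test of SES against 0.

    A Shapiro-Wilk screen chooses between the one-sample t-test and the
    Wilcoxon signed-rank test (used when normality is rejected).
    """
    x = np.asarray(pd.Series(ses_values).dropna(), float)
    if len(x) < 3:
        raise ValidationError("need >= 3 defined SES values")
    if np.ptp(x) == 0:
        return {"test_used": "degenerate", "statistic": np.nan,
                "p": np.nan, "n": len(x), "mean": float(x.mean())}
    sw_p = stats.shapiro(x).pvalue
    if sw_p >= alpha_normality:
        res = stats.ttest_1samp(x, 0.0)
        used = "t"
    else:
        res = stats.wilcoxon(x)
        used = "wilcoxon"
    return {"test_used": used, "statistic": float(res.statistic),
            "p": float(res.pvalue), "n": len(x), "mean": float(x.mean()),
            "shapiro_p": float(sw_p)}
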
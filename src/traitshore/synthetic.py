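"""Synthetic seaweed assemblages with known assembly processes.

Generates (i) species x trait tables with the block-correlation
structure the analysis assumes — an economics-like trade-off between
thin, high-surface-area thalli and thick, structurally invested ones —
and (ii) zoned quadrat x cover community matrices assembled at random,
by environmental filtering, or by limiting similarity. Because the
assembly process is known, every downstream stage (trait space, groups,
alpha/beta diversity, null models, inference) can be tested without any
field data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ROCKPOOL_THRESHOLD,
    ZONE_INDICATORS,
    ZONES,
    CommunityMatrix,
    TraitTable,
    ValidationError,
)

# ---------------------------------------------------------------------------
# trait generation

# Continuous traits in generation order; pneumatocysts is drawn separately.
_CONT = ["sta", "sa_v", "thickness", "tdmc", "c_n",
         "length", "branching_order", "sa_p"]

# Log-scale location and spread per continuous trait (rough field ranges:
# STA in mm2/g, thickness in mm, length in cm, ...).
_LOG_MU = {"sta": np.log(50.0), "sa_v": np.log(20.0),
           "thickness": np.log(0.5), "tdmc": np.log(0.2),
           "c_n": np.log(15.0), "length": np.log(10.0),
           "branching_order": np.log(2.0), "sa_p": np.log(5.0)}
_LOG_SD = {"sta": 0.8, "sa_v": 0.7, "thickness": 0.7, "tdmc": 0.4,
           "c_n": 0.5, "length": 1.0, "branching_order": 0.8, "sa_p": 0.7}

#: Probability that a species carries pneumatocysts (gas bladders).
PNEUMATOCYST_PROB = 0.1


def _latent_correlation() -> np.ndarray:
    """Block correlation among log-traits.

    Within blocks |r| >= 0.4 (photosynthesis traits trade off against
    thickness; structural traits covary; branching against SA:P), between
    blocks |r| <= 0.2, so that the leading trait axis is the
    surface-vs-structure trade-off.
    """
    idx = {t: i for i, t in enumerate(_CONT)}
    R = np.eye(len(_CONT))

    def put(a, b, r):
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    # photosynthesis block
    put("sta", "sa_v", 0.6)
    put("sta", "thickness", -0.6)
    put("sa_v", "thickness", -0.6)
    # structure block
    put("tdmc", "c_n", 0.6)
    # space-use block
    put("length", "branching_order", 0.5)
    put("branching_order", "sa_p", -0.5)
    put("length", "sa_p", -0.25)
    # weak between-block leakage along the trade-off axis
    for a in ("tdmc", "c_n"):
        put("sta", a, -0.15)
        put("sa_v", a, -0.15)
        put("thickness", a, 0.15)

    # guard positive semi-definiteness (clip tiny negative modes)
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def generate_traits(n_species: int = 50, rng_seed: int = 0) -> TraitTable:
    """Draw a species x 9 trait table with block-correlated traits.

    Continuous traits are log-normal with the correlation structure of
    :func:`_latent_correlation`; branching order is the rounded latent
    (non-negative integer, zeros = unbranched thalli); pneumatocysts are
    Bernoulli(0.1). Deterministic for a fixed seed.
    """
    if n_species < 3:
        raise ValidationError("n_species must be >= 3")
    rng = np.random.default_rng(rng_seed)
    R = _latent_correlation()
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n_species, len(_CONT))) @ L.T
    data = {}
    for j, t in enumerate(_CONT):
        vals = np.exp(_LOG_MU[t] + _LOG_SD[t] * z[:, j])
        if t == "branching_order":
            vals = np.maximum(np.rint(vals - 1.0), 0.0)  # unbranched -> 0
        data[t] = vals
    data["pneumatocysts"] = (
        rng.random(n_species) < PNEUMATOCYST_PROB).astype(float)
    species = [f"sp{i + 1:03d}" for i in range(n_species)]
    df = pd.DataFrame(data, index=species)[
        ["sta", "sa_v", "thickness", "tdmc", "c_n",
         "length", "pneumatocysts", "branching_order", "sa_p"]]
    return TraitTable(df)


# ---------------------------------------------------------------------------
# community assembly

@dataclass(frozen=True)
class AssemblyScenario:
    """Parameters of a synthetic assembly process.

    process
        "random" (neutral draws), "filtering" (inclusion probability
        decays with trait distance to a zone optimum, compressing trait
        space) or "limiting_similarity" (sequential admission favouring
        species distant from residents, spreading trait space).
    zone_richness_targets
        Expected per-quadrat richness for (low, mid, upper); must be
        non-increasing with shore height.
    filter_strength
        Gaussian filter width sigma_f on the Gower distance scale (the
        default 0.05 is a strong filter; sigma_f -> inf recovers random
        assembly).
    similarity_decay
        Limiting-similarity rate lambda; admission weight of a candidate
        is min over residents of 1 - exp(-lambda * d).
    """

    process: str = "random"
    n_species: int = 50
    n_quadrats_per_cell: int = 14
    zone_richness_targets: tuple = (16, 12, 8)
    filter_strength: float = 0.05
    similarity_decay: float = 5.0
    n_pool_only: int = 5
    total_cover_range: tuple = (60.0, 160.0)
    rng_seed: int = 0

    def __post_init__(self):
        if self.process not in ("random", "filtering", "limiting_similarity"):
            raise ValidationError(f"unknown process {self.process!r}")
        t = self.zone_richness_targets
        if len(t) != 3 or any(x < 1 for x in t):
            raise ValidationError("three zone richness targets >= 1 required")
        if not (t[0] >= t[1] >= t[2]):
            raise ValidationError(
                "richness targets must be non-increasing low->upper")
        if self.filter_strength <= 0:
            raise ValidationError("filter_strength must be > 0")
        if self.similarity_decay < 0:
            raise ValidationError("similarity_decay must be >= 0")

    def replace(self, **kw) -> "AssemblyScenario":
        return dataclasses.replace(self, **kw)


def _broken_stick(n: int, rng: np.random.Generator) -> np.ndarray:
    """Relative abundances from breaking the unit stick at n-1 points."""
    if n == 1:
        return np.ones(1)
    cuts = np.sort(rng.random(n - 1))
    parts = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
    return rng.permutation(parts)


def _zone_optima(D: np.ndarray, rng: np.random.Generator) -> dict:
    """Zone-specific optimum species: medoids of three disjoint random
    species subsets (guarantees distinct optima without tuning)."""
    n = D.shape[0]
    perm = rng.permutation(n)
    thirds = np.array_split(perm, 3)
    optima = {}
    for z, sub in zip(ZONES, thirds):
        sums = D[np.ix_(sub, sub)].sum(axis=1)
        optima[z] = int(sub[int(np.argmin(sums))])
    return optima


def _sample_filtering(candidates, S, D, optimum, sigma, rng):
    d = D[candidates, optimum]
    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    if not np.isfinite(w).all() or w.sum() <= 0:
        w = np.ones_like(w)
    return rng.choice(candidates, size=S, replace=False, p=w / w.sum())


def _sample_limiting(candidates, S, D, lam, rng):
    chosen = [int(rng.choice(candidates))]
    remaining = [c for c in candidates if c != chosen[0]]
    while len(chosen) < S:
        d = D[np.ix_(remaining, chosen)]
        w = (1.0 - np.exp(-lam * d)).min(axis=1)
        if w.sum() <= 0:
            w = np.ones(len(remaining))
        pick = int(rng.choice(len(remaining), p=w / w.sum()))
        chosen.append(remaining.pop(pick))
    return np.array(chosen)


def generate_communities(traits: TraitTable,
                         scenario: AssemblyScenario) -> CommunityMatrix:
    """Assemble a zoned community matrix under a known process.

    Produces 3 zones x 2 habitats x ``n_quadrats_per_cell`` quadrats.
    Per-quadrat richness is Poisson around the zone target (clipped to
    [3, pool size]); covers are broken-stick proportions scaled by a
    multi-layer total that may exceed 100%. A designated pool-only
    species subset occurs only in rock-pool quadrats.
    """
    from .trait_space import gower_distance, preprocess_traits

    if traits.n_species != scenario.n_species:
        scenario = scenario.replace(n_species=traits.n_species)
    n = traits.n_species
    if max(scenario.zone_richness_targets) > n:
        raise ValidationError("richness target exceeds species-pool size")
    rng = np.random.default_rng(scenario.rng_seed)
    D = gower_distance(preprocess_traits(traits)).values

    pool_only = rng.choice(n, size=min(scenario.n_pool_only, max(n - 3, 0)),
                           replace=False)
    pool_only_set = set(int(i) for i in pool_only)
    optima = (_zone_optima(D, rng)
              if scenario.process == "filtering" else None)

    rows, meta_rows, qids = [], [], []
    sites = ["Oxwich", "Bracelet", "Overton", "Rhossili"]
    q = 0
    for zi, zone in enumerate(ZONES):
        target = scenario.zone_richness_targets[zi]
        for rp in (True, False):
            for _ in range(scenario.n_quadrats_per_cell):
                cands = np.arange(n) if rp else np.array(
                    [i for i in range(n) if i not in pool_only_set])
                S = int(np.clip(rng.poisson(target), 3, len(cands)))
                if scenario.process == "random":
                    sel = rng.choice(cands, size=S, replace=False)
                elif scenario.process == "filtering":
                    sel = _sample_filtering(cands, S, D, optima[zone],
                                            scenario.filter_strength, rng)
                else:
                    sel = _sample_limiting(list(cands), S, D,
                                           scenario.similarity_decay, rng)
                if rp and pool_only_set and not (
                        set(int(s) for s in sel) & pool_only_set):
                    # rock-pool quadrats host at least one pool specialist
                    drop = int(rng.integers(len(sel)))
                    sel = np.array(sel)
                    sel[drop] = int(rng.choice(pool_only))
                total = rng.uniform(*scenario.total_cover_range)
                cover = np.zeros(n)
                cover[np.asarray(sel, int)] = _broken_stick(len(sel),
                                                            rng) * total
                rows.append(cover)
                rp_cover = (rng.uniform(ROCKPOOL_THRESHOLD, 40.0) if rp
                            else rng.uniform(0.0, ROCKPOOL_THRESHOLD * 0.999))
                q += 1
                qids.append(f"q{q:03d}")
                meta_rows.append({"site": sites[int(rng.integers(4))],
                                  "zone": zone,
                                  "rockpool_cover_pct": rp_cover})
    cover = pd.DataFrame(np.asarray(rows), index=qids,
                         columns=traits.species_ids)
    meta = pd.DataFrame(meta_rows, index=qids)
    return CommunityMatrix(cover, meta)


def generate_nested_communities(traits: TraitTable,
                                n_quadrats_per_cell: int = 14,
                                zone_richness_targets=(16, 12, 8),
                                pool_sizes=(40, 24, 13),
                                n_reserve: int = 10,
                                rng_seed: int = 0) -> CommunityMatrix:
    """Zone pools that are mostly nested, with a few replacements.

    Emulates intertidal attrition: the low-shore pool spans the whole
    trait space; mid- and upper-shore pools shrink towards the centre of
    the trait space (hence functional change is dominated by nestedness)
    while a handful of zone-exclusive species, themselves central,
    generate taxonomic turnover without expanding the hull.
    """
    from .trait_space import gower_distance, preprocess_traits

    n = traits.n_species
    rng = np.random.default_rng(rng_seed)
    D = gower_distance(preprocess_traits(traits)).values
    centrality = D.sum(axis=1)  # low = central
    order = np.argsort(centrality)

    # reserve mid-rank species as turnover donors for mid/upper zones
    reserve = [int(i) for i in order[10:10 + n_reserve]]
    low_pool = [i for i in range(n) if i not in set(reserve)][: pool_sizes[0]]
    low_central = [int(i) for i in order if int(i) in set(low_pool)]
    mid_pool = low_central[: pool_sizes[1] - 4] + reserve[:4]
    upper_pool = low_central[: pool_sizes[2] - 3] + reserve[4:7]
    pools = {"low": np.array(low_pool), "mid": np.array(mid_pool),
             "upper": np.array(upper_pool)}

    rows, meta_rows, qids = [], [], []
    q = 0
    for zi, zone in enumerate(ZONES):
        pool = pools[zone]
        target = min(zone_richness_targets[zi], len(pool))
        for rp in (True, False):
            for _ in range(n_quadrats_per_cell):
                S = int(np.clip(rng.poisson(target), 3, len(pool)))
                sel = rng.choice(pool, size=S, replace=False)
                total = rng.uniform(60.0, 160.0)
                cover = np.zeros(n)
                cover[sel] = _broken_stick(S, rng) * total
                q += 1
                qids.append(f"q{q:03d}")
                rows.append(cover)
                meta_rows.append({
                    "site": "synthetic", "zone": zone,
                    "rockpool_cover_pct": (rng.uniform(5, 40) if rp
                                           else rng.uniform(0, 4.99))})
    cover = pd.DataFrame(np.asarray(rows), index=qids,
                         columns=traits.species_ids)
    return CommunityMatrix(cover, pd.DataFrame(meta_rows, index=qids))


# ---------------------------------------------------------------------------
# survey-protocol operations

def assign_zone(cover_row, indicator_map=None) -> str:
    """Zone whose indicator species jointly exceed 80% of total cover.

    Returns ``"transition"`` when no zone's indicators exceed the
    threshold (strictly: exactly 80% is a transition); such quadrats are
    excluded from analysis by default.
    """
    indicator_map = indicator_map or ZONE_INDICATORS
    row = pd.Series(cover_row, dtype=float) if not isinstance(
        cover_row, pd.Series) else cover_row.astype(float)
    total = row.sum()
    if total <= 0:
        raise ValidationError("cannot assign a zone to an all-zero quadrat")
    for zone, indicators in indicator_map.items():
        frac = row.reindex(list(indicators)).fillna(0.0).sum() / total
        if frac > 0.80:
            return zone
    return "transition"


def binarize_rockpool(rockpool_cover_pct: float) -> str:
    """Binary rock-pool habitat: present at >= 5% cover."""
    if rockpool_cover_pct < 0:
        raise ValidationError("rock-pool cover must be >= 0")
    return "present" if rockpool_cover_pct >= ROCKPOOL_THRESHOLD else "absent"


def balance_subset(cm: CommunityMatrix, n_per_cell: int,
                   rng_seed: int = 0) -> CommunityMatrix:
    """Random balanced subset: n_per_cell quadrats per zone x habitat cell.

    Mirrors the survey design step of subsetting to equal representation
    (e.g. 14 per cell -> 84 quadrats). Deterministic per seed; raises if
    any cell is undersized.
    """
    rng = np.random.default_rng(rng_seed)
    habitat = cm.rockpool_present.map({True: "present", False: "absent"})
    keep = []
    for zone in ZONES:
        for hab in ("present", "absent"):
            cell = [qid for qid in cm.quadrat_ids
                    if cm.zone[qid] == zone and habitat[qid] == hab]
            if len(cell) < n_per_cell:
                raise ValidationError(
                    f"cell (zone={zone}, rockpool={hab}) has {len(cell)} "
                    f"quadrats; {n_per_cell} required")
            keep.extend(sorted(
                rng.choice(cell, size=n_per_cell, replace=False)))
    return cm.subset(keep)
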
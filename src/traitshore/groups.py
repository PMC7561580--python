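"""Emergent functional groups.

Species are partitioned by k-medoids (PAM) on the Gower dissimilarity;
the number of groups is chosen as the largest k for which every pairwise
group contrast is significant under PERMANOVA at alpha = 0.05. Group
richness then gives a redundancy-aware counterpart of species richness:
it only declines when a whole region of trait space is vacated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ZONES, CommunityMatrix, ValidationError
from .trait_space import DistanceMatrix


@dataclass
class EmergentGrouping:
    k: int
    assignment: pd.Series            # species -> group id (0-based)
    medoids: list                    # species label per group
    total_cost: float                # sum of dissimilarities to own medoid
    criterion_met: bool = True
    selection_table: pd.DataFrame = field(
        default_factory=pd.DataFrame, repr=False)

    def groups(self) -> dict:
        return {g: list(idx) for g, idx in
                self.assignment.groupby(self.assignment).groups.items()}

    def to_csv(self, path) -> None:
        self.assignment.rename("group").rename_axis("species").to_csv(path)


# ---------------------------------------------------------------------------
# PAM k-medoids

def _assignment_cost(D: np.ndarray, med: np.ndarray):
    d = D[:, med]
    lab = np.argmin(d, axis=1)
    return lab, float(d[np.arange(len(D)), lab].sum())


def k_medoids(D: DistanceMatrix, k: int, rng_seed: int = 0) -> EmergentGrouping:
    """PAM: deterministic greedy BUILD then steepest-descent SWAP.

    Accepts the best cost-lowering medoid<->non-medoid swap until none
    exists; ties broken by lowest species index, so the result is
    deterministic (the seed is accepted for interface symmetry but PAM
    here has no random step).
    """
    n = D.n
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    M = D.values

    # BUILD
    med = [int(np.argmin(M.sum(axis=1)))]
    while len(med) < k:
        best_gain, best_j = -np.inf, None
        cur = M[:, med].min(axis=1)
        for j in range(n):
            if j in med:
                continue
            gain = np.maximum(cur - M[:, j], 0.0).sum()
            if gain > best_gain + 1e-15:
                best_gain, best_j = gain, j
        med.append(best_j)

    med = np.array(sorted(med))
    lab, cost = _assignment_cost(M, med)
    # SWAP
    improved = True
    while improved:
        improved = False
        best = (cost, None)
        for mi in range(k):
            for h in range(n):
                if h in med:
                    continue
                trial = med.copy()
                trial[mi] = h
                _, c = _assignment_cost(M, trial)
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is not None:
            med = np.sort(best[1])
            lab, cost = _assignment_cost(M, med)
            improved = True

    # relabel groups by medoid order for determinism
    order = {m: g for g, m in enumerate(med)}
    assignment = pd.Series([order[med[l]] for l in lab], index=D.labels)
    return EmergentGrouping(k=k, assignment=assignment,
                            medoids=[D.labels[m] for m in med],
                            total_cost=cost)


# ---------------------------------------------------------------------------
# PERMANOVA (Anderson's distance-based pseudo-F)

def permanova(D: DistanceMatrix, labels, n_perm: int = 999,
              rng_seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA on a dissimilarity matrix.

    pseudo-F = ((SST - SSW)/(a-1)) / (SSW/(n-a)) with sums of squared
    dissimilarities; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    lab = np.asarray(pd.factorize(np.asarray(labels))[0])
    n = D.n
    if len(lab) != n:
        raise ValidationError("labels length must match matrix size")
    groups, counts = np.unique(lab, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs >= 2 members")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    D2 = D.values ** 2
    sst = D2[np.triu_indices(n, 1)].sum() / n
    a = len(groups)

    def ssw(perm_lab):
        s = 0.0
        for g, ng in zip(groups, counts):
            idx = np.flatnonzero(perm_lab == g)
            s += D2[np.ix_(idx, idx)].sum() / (2.0 * ng)
        return s

    ssw_obs = ssw(lab)
    denom_df = n - a
    f_obs = ((sst - ssw_obs) / (a - 1)) / (ssw_obs / denom_df)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_perm):
        pl = rng.permutation(lab)
        sw = ssw(pl)
        f = ((sst - sw) / (a - 1)) / (sw / denom_df)
        if f >= f_obs:
            count += 1
    return float(f_obs), (1.0 + count) / (1.0 + n_perm)


def _pairwise_permanova(D: DistanceMatrix, grouping: EmergentGrouping,
                        n_perm, rng_seed, adjust):
    pos = {s: i for i, s in enumerate(D.labels)}
    rows = []
    gids = sorted(grouping.groups())
    for i, gi in enumerate(gids):
        for gj in gids[i + 1:]:
            members = (grouping.groups()[gi], grouping.groups()[gj])
            idx = [pos[s] for g in members for s in g]
            lab = [0] * len(members[0]) + [1] * len(members[1])
            sub = DistanceMatrix([D.labels[i] for i in idx],
                                 D.values[np.ix_(idx, idx)])
            f, p = permanova(sub, lab, n_perm=n_perm,
                             rng_seed=rng_seed + 31 * gi + gj)
            rows.append({"group_a": gi, "group_b": gj,
                         "pseudo_F": f, "p": p})
    tab = pd.DataFrame(rows)
    if adjust == "bh":
        tab["p_adj"] = multipletests(tab["p"], method="fdr_bh")[1]
    elif adjust == "none":
        tab["p_adj"] = tab["p"]
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return tab


def select_k(D: DistanceMatrix, k_range=range(2, 11), alpha: float = 0.05,
             n_perm: int = 999, rng_seed: int = 0,
             adjust: str = "bh") -> EmergentGrouping:
    """Largest k whose every pairwise group contrast is significant.

    For each candidate k the species are clustered and all pairwise
    PERMANOVA contrasts run; p-values are Benjamini-Hochberg adjusted by
    default before the alpha screen. If no k qualifies the k=2 grouping
    is returned flagged ``criterion_met=False``.
    """
    tables = []
    best = None
    for k in k_range:
        if k > D.n:
            break
        grouping = k_medoids(D, k, rng_seed=rng_seed)
        sizes = grouping.assignment.value_counts()
        if len(sizes) < k or sizes.min() < 2:
            tables.append(pd.DataFrame(
                [{"k": k, "group_a": int(sizes.idxmin()), "group_b": -1,
                  "pseudo_F": np.nan, "p": np.nan, "p_adj": np.nan,
                  "all_significant": False}]))
            continue
        tab = _pairwise_permanova(D, grouping, n_perm, rng_seed + 1000 * k,
                                  adjust)
        tab.insert(0, "k", k)
        ok = bool((tab["p_adj"] <= alpha).all())
        tab["all_significant"] = ok
        tables.append(tab)
        if ok:
            best = grouping
    selection = (pd.concat(tables, ignore_index=True)
                 if tables else pd.DataFrame())
    if best is None:
        best = k_medoids(D, 2, rng_seed=rng_seed)
        best.criterion_met = False
    best.selection_table = selection
    return best


# ---------------------------------------------------------------------------
# group richness

def group_richness(cm: CommunityMatrix, grouping: EmergentGrouping) -> dict:
    """Emergent-group richness per quadrat and per zone.

    Returns quadrat- and zone-scale counts of groups with at least one
    present species, per-group species counts by zone, and the percent
    net change in group occupancy from low to upper shore.
    """
    missing = set(cm.species_ids) - set(grouping.assignment.index)
    if missing:
        raise ValidationError(
            f"species not covered by the grouping: {sorted(missing)}")
    gvec = grouping.assignment.reindex(cm.species_ids).to_numpy()
    pres = cm.presence().to_numpy()

    def count_groups(mask):
        return len(set(gvec[mask])) if mask.any() else 0

    quadrat = pd.Series([count_groups(pres[i]) for i in range(len(pres))],
                        index=cm.quadrat_ids, name="group_richness")
    zone_pres = cm.zone_presence()
    zone = pd.Series({z: count_groups(zone_pres.loc[z].to_numpy())
                      for z in zone_pres.index}, name="group_richness")
    per_group = pd.DataFrame(
        {z: pd.Series(gvec[zone_pres.loc[z].to_numpy()]).value_counts()
         for z in zone_pres.index}).fillna(0).astype(int).sort_index()
    pct_net_loss = None
    if {"low", "upper"} <= set(zone_pres.index):
        lo = per_group["low"]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct_net_loss = (100.0 * (lo - per_group["upper"]) /
                            lo.replace(0, np.nan)).rename("pct_net_loss")
    return {"quadrat": quadrat, "zone": zone.reindex(
        [z for z in ZONES if z in zone.index]),
        "per_group_by_zone": per_group, "pct_net_loss": pct_net_loss}
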
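"""Zone x rock-pool inference layer.

Count responses (species and emergent-group richness) are modelled with
quasi-Poisson GLMs (log link, dispersion estimated from the Pearson
chi-square); continuous functional metrics and SES with Gaussian linear
models. Terms enter sequentially in the fixed order Zone, RP (rock-pool
presence), Zone x RP, and each term is tested with an analysis-of-
deviance (or sequential sum-of-squares) F test. Zone differences are
summarised as compact letter displays from pairwise post-hoc contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import ZONES, ValidationError

TERM_ORDER = ("zone", "rockpool", "zone:rockpool")


@dataclass
class ModelFit:
    response: str
    family: str                       # "quasipoisson" | "gaussian"
    anova: pd.DataFrame               # term, df, deviance/SS, resid, F, p
    dispersion: float
    nobs: int
    coefficients: pd.Series = field(default_factory=pd.Series, repr=False)
    posthoc_letters: dict | None = None
    n_dropped: int = 0

    def to_csv(self, path) -> None:
        self.anova.to_csv(path, index=False)


def _design_frame(response, zone, rockpool) -> pd.DataFrame:
    df = pd.DataFrame({
        "y": np.asarray(response, float),
        "zone": pd.Categorical(zone, categories=list(ZONES), ordered=True),
        "rockpool": pd.Categorical(
            np.where(np.asarray(rockpool, bool), "present", "absent"),
            categories=["absent", "present"]),
    })
    return df


def fit_glm_quasipoisson(response_counts, zone, rockpool,
                         posthoc: bool = True) -> ModelFit:
    """Quasi-Poisson GLM with sequential analysis of deviance.

    Coefficients are the plain Poisson MLEs; dispersion phi = Pearson
    chi2 / df_resid only rescales inference. Each term's F statistic is
    (delta deviance / delta df) / phi against the full-model residual df.
    """
    y = np.asarray(response_counts, float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValidationError("count response must be non-negative integers")
    if y.sum() == 0:
        raise ValidationError("all-zero count response; degenerate fit")
    df = _design_frame(y, zone, rockpool)
    formulas = ["y ~ 1", "y ~ zone", "y ~ zone + rockpool",
                "y ~ zone * rockpool"]
    fits = [smf.glm(f, data=df, family=sm.families.Poisson()).fit()
            for f in formulas]
    full = fits[-1]
    phi = float(full.pearson_chi2 / full.df_resid)
    rows = []
    for name, reduced, fuller in zip(TERM_ORDER, fits[:-1], fits[1:]):
        ddev = reduced.deviance - fuller.deviance
        ddf = reduced.df_resid - fuller.df_resid
        if ddev < 1e-10:      # saturated / no-effect term
            F = 0.0
        elif phi <= 0:
            F = np.inf
        else:
            F = (ddev / ddf) / phi
        p = float(stats.f.sf(F, ddf, full.df_resid))
        rows.append({"term": name, "df": int(ddf), "deviance": float(ddev),
                     "resid_deviance": float(fuller.deviance),
                     "F": float(F), "p": p})
    anova = pd.DataFrame(rows)
    letters = _glm_zone_letters(df, phi) if posthoc else None
    return ModelFit("counts", "quasipoisson", anova, phi, len(df),
                    full.params, letters)


def fit_lm(response, zone, rockpool, posthoc: bool = True) -> ModelFit:
    """Gaussian linear model with sequential (type-I) sums of squares.

    Rows with missing responses (e.g. degenerate-FRic quadrats) are
    dropped and counted.
    """
    y = np.asarray(response, float)
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    df = _design_frame(y[keep], np.asarray(zone)[keep],
                       np.asarray(rockpool)[keep])
    fit = smf.ols("y ~ zone * rockpool", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValidationError("rank-deficient design (aliased term)")
    tab = sm.stats.anova_lm(fit, typ=1)
    rows = []
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    running = float(tab["sum_sq"].sum())
    for src, name in zip(["zone", "rockpool", "zone:rockpool"], TERM_ORDER):
        running -= float(tab.loc[src, "sum_sq"])
        rows.append({"term": name, "df": int(tab.loc[src, "df"]),
                     "sum_sq": float(tab.loc[src, "sum_sq"]),
                     "resid_ss": running,
                     "F": float(tab.loc[src, "F"]),
                     "p": float(tab.loc[src, "PR(>F)"])})
    anova = pd.DataFrame(rows)
    sigma2 = resid_ss / float(tab.loc["Residual", "df"])
    letters = _tukey_zone_letters(df) if posthoc else None
    return ModelFit("gaussian", "gaussian", anova, sigma2, len(df),
                    fit.params, letters, n_dropped)


# ---------------------------------------------------------------------------
# compact letter display

def _compact_letters(groups, nsd_pairs, means) -> dict:
    """Letters such that groups sharing a letter are not significantly
    different: one letter per maximal clique of the 'not different'
    graph (brute force; the zone factor has 3 levels)."""
    nsd = {frozenset(p) for p in nsd_pairs}

    def is_clique(subset):
        return all(frozenset((a, b)) in nsd
                   for a, b in itertools.combinations(subset, 2))

    cliques = []
    for r in range(len(groups), 0, -1):
        for combo in itertools.combinations(groups, r):
            if is_clique(combo) and not any(
                    set(combo) <= set(c) for c in cliques):
                cliques.append(combo)
    cliques.sort(key=lambda c: min(means[g] for g in c))
    letters = {g: "" for g in groups}
    for i, c in enumerate(cliques):
        for g in c:
            letters[g] += chr(ord("a") + i)
    return letters


def _tukey_zone_letters(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    zones = [z for z in ZONES if z in set(df["zone"])]
    if len(zones) < 2:
        raise ValidationError("post-hoc letters need >= 2 zones")
    res = pairwise_tukeyhsd(df["y"], np.asarray(df["zone"]), alpha=alpha)
    tab = pd.DataFrame(res.summary().data[1:],
                       columns=res.summary().data[0])
    nsd = [(r["group1"], r["group2"]) for _, r in tab.iterrows()
           if not r["reject"]]
    means = df.groupby("zone", observed=True)["y"].mean().to_dict()
    return _compact_letters(zones, nsd, means)


def _glm_zone_letters(df: pd.DataFrame, phi: float,
                      alpha: float = 0.05) -> dict:
    """Pairwise Wald z contrasts among zone levels of the additive
    quasi-Poisson model, BH-adjusted."""
    zones = [z for z in ZONES if z in set(df["zone"])]
    fit = smf.glm("y ~ zone + rockpool", data=df,
                  family=sm.families.Poisson()).fit(scale=phi)
    names = list(fit.params.index)
    pairs, pvals = [], []
    for a, b in itertools.combinations(zones, 2):
        vec = np.zeros(len(names))
        for z, sign in ((a, 1.0), (b, -1.0)):
            col = f"zone[T.{z}]"
            if col in names:
                vec[names.index(col)] = sign
        test = fit.t_test(vec)
        pairs.append((a, b))
        pvals.append(float(np.atleast_1d(test.pvalue)[0]))
    adj = multipletests(pvals, method="fdr_bh")[1]
    nsd = [p for p, pa in zip(pairs, adj) if pa > alpha]
    means = df.groupby("zone", observed=True)["y"].mean().to_dict()
    return _compact_letters(zones, nsd, means)


def posthoc_zone_letters(response, zone, rockpool,
                         family: str = "gaussian",
                         alpha: float = 0.05) -> dict:
    """Compact letter display of pairwise zone contrasts.

    Tukey HSD for Gaussian responses; BH-adjusted Wald z contrasts on
    the additive quasi-Poisson model for counts.
    """
    y = np.asarray(response, float)
    keep = np.isfinite(y)
    df = _design_frame(y[keep], np.asarray(zone)[keep],
                       np.asarray(rockpool)[keep])
    if df["zone"].nunique() < 2:
        raise ValidationError("need >= 2 zones")
    if family == "gaussian":
        return _tukey_zone_letters(df, alpha)
    full = smf.glm("y ~ zone * rockpool", data=df,
                   family=sm.families.Poisson()).fit()
    phi = float(full.pearson_chi2 / full.df_resid)
    return _glm_zone_letters(df, phi, alpha)


# ---------------------------------------------------------------------------
# diagnostics

def richness_fd_relationship(alpha_records: pd.DataFrame) -> dict:
    """R^2 of emergent-group richness on species richness (quadrat
    scale), plus the mean FRic / group richness per richness value — the
    saturation diagnostic."""
    q = alpha_records[alpha_records["scale"] == "quadrat"]
    x = q["species_richness"].to_numpy(float)
    g = q["group_richness"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("species richness is constant; R^2 undefined")
    fit = sm.OLS(g, sm.add_constant(x)).fit()
    curve = (q.groupby("species_richness")
             .agg(mean_group_richness=("group_richness", "mean"),
                  mean_fric_scaled=("fric_scaled", "mean"),
                  n=("unit", "size"))
             .reset_index())
    return {"r2": float(fit.rsquared), "slope": float(fit.params[1]),
            "curve": curve}
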
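"""Model/Results facade over the full analysis pipeline.

`FunctionalDiversityModel` holds a trait table and a community matrix
plus the analysis configuration; `fit()` runs trait space construction,
emergent-group selection, alpha and beta diversity, trait-shuffling
null models and the zone x rock-pool inference layer, returning a
`FunctionalDiversityResults` with every table and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import inference as inf_mod
from . import nulls as nulls_mod
from .containers import CommunityMatrix, TraitTable
from .groups import EmergentGrouping, group_richness, select_k
from .trait_space import (
    FunctionalSpace,
    build_functional_space,
    gower_distance,
    preprocess_traits,
)


@dataclass
class FunctionalDiversityResults:
    """Estimates, SES tables, inference tables and diagnostics."""

    space: FunctionalSpace
    grouping: EmergentGrouping
    alpha: pd.DataFrame
    beta: pd.DataFrame
    ses: dict = field(default_factory=dict)        # (metric, constraint) -> df
    ses_tests: dict = field(default_factory=dict)  # same keys -> test dict
    anova: dict = field(default_factory=dict)      # response -> ModelFit
    group_report: dict = field(default_factory=dict)
    relationship: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Functional diversity of zoned assemblages",
                 "=" * 42]
        fs = self.space
        lines.append(
            f"Trait space: {len(fs.labels)} species, {fs.m} retained axes "
            f"({100 * fs.inertia_explained[:2].sum():.0f}% inertia on the "
            f"first two), correction: {fs.correction_method}")
        g = self.grouping
        lines.append(f"Emergent groups: k = {g.k}"
                     + ("" if g.criterion_met else " (criterion unmet)"))
        zs = alpha_mod.zone_summary(self.alpha)
        lines.append("\nZone-scale alpha diversity (low -> upper):")
        lines.append(zs[["species_richness", "group_richness",
                         "fric_scaled", "fdis"]].round(3).to_string())
        if len(self.beta):
            lines.append("\nMultiple-site beta diversity across zones:")
            lines.append(self.beta.round(3).to_string(index=False))
        if self.ses_tests:
            lines.append("\nSES vs. null (trait shuffling):")
            for (metric, constraint), t in self.ses_tests.items():
                lines.append(
                    f"  {metric} [{constraint}]: mean SES = "
                    f"{t['mean']:+.3f}, {t['test_used']} test p = "
                    f"{t['p']:.3g} (n = {t['n']})")
        if self.anova:
            lines.append("\nZone x rock-pool models "
                         "(sequential F tests):")
            for resp, fit in self.anova.items():
                lines.append(f"  {resp} [{fit.family}]"
                             + (f", zone letters {fit.posthoc_letters}"
                                if fit.posthoc_letters else ""))
                lines.append(
                    fit.anova.round(4).to_string(index=False, col_space=9))
        if self.relationship:
            lines.append(
                f"\nGroup richness ~ species richness: "
                f"R^2 = {self.relationship['r2']:.2f}")
        return "\n".join(lines)


class FunctionalDiversityModel:
    """Trait-based diversity analysis of a zoned community matrix.

    Parameters
    ----------
    traits, community : TraitTable, CommunityMatrix
    m_axes : retained ordination axes (default 4); ``quality_rule``
        instead picks the dimensionality minimising the squared
        deviation between Gower and embedded distances.
    k_range, alpha, n_perm : emergent-group selection settings.
    n_null : trait-shuffling replicates per quadrat (default 999).
    exclude_indicators : drop the six zone-defining fucoids/kelp
        (sensitivity analysis).
    """

    def __init__(self, traits: TraitTable, community: CommunityMatrix,
                 m_axes: int = 4, quality_rule: bool = False,
                 correction: str = "cailliez", k_range=range(2, 11),
                 alpha: float = 0.05, n_perm: int = 999,
                 n_null: int = 999, adjust: str = "bh",
                 exclude_indicators: bool = False,
                 mc_draws: int = 100_000):
        community.check_species_covered(traits)
        if exclude_indicators:
            drop = [s for s in alpha_mod.indicator_species()
                    if s in community.species_ids]
            community = community.drop_species(drop)
        self.traits = traits
        self.community = community
        self.m_axes = m_axes
        self.quality_rule = quality_rule
        self.correction = correction
        self.k_range = k_range
        self.alpha_level = alpha
        self.n_perm = n_perm
        self.n_null = n_null
        self.adjust = adjust
        self.mc_draws = mc_draws

    @classmethod
    def from_csv(cls, trait_path, community_path, **kwargs
                 ) -> "FunctionalDiversityModel":
        from .io import read_community_csv, read_trait_csv
        traits = read_trait_csv(trait_path)
        return cls(traits, read_community_csv(community_path, traits),
                   **kwargs)

    @classmethod
    def from_synthetic(cls, scenario=None, n_species: int = 50,
                       rng_seed: int = 0, **kwargs
                       ) -> "FunctionalDiversityModel":
        from .synthetic import AssemblyScenario, generate_communities, \
            generate_traits
        scenario = scenario or AssemblyScenario(rng_seed=rng_seed,
                                                n_species=n_species)
        traits = generate_traits(scenario.n_species, rng_seed=rng_seed)
        return cls(traits, generate_communities(traits, scenario), **kwargs)

    def build_space(self) -> FunctionalSpace:
        return build_functional_space(self.traits, m=self.m_axes,
                                      quality_rule=self.quality_rule,
                                      correction=self.correction)

    def fit(self, seed: int = 0, run_nulls: bool = True,
            run_inference: bool = True,
            constraints=("none", "within_zone")
            ) -> FunctionalDiversityResults:
        cm = self.community
        fs = self.build_space()
        D = gower_distance(preprocess_traits(self.traits))
        grouping = select_k(D, k_range=self.k_range,
                            alpha=self.alpha_level, n_perm=self.n_perm,
                            rng_seed=seed, adjust=self.adjust)
        alpha = alpha_mod.alpha_table(cm, fs, grouping)
        beta = beta_mod.beta_report(cm, fs, mc_draws=self.mc_draws,
                                    rng_seed=seed)
        res = FunctionalDiversityResults(
            space=fs, grouping=grouping, alpha=alpha, beta=beta,
            group_report=group_richness(cm, grouping),
            config={"m_axes": fs.m, "n_null": self.n_null,
                    "n_perm": self.n_perm, "seed": seed})

        if run_nulls:
            for metric in nulls_mod.METRICS:
                for constraint in constraints:
                    tab = nulls_mod.ses(cm, fs, metric,
                                        n_null=self.n_null,
                                        constraint=constraint,
                                        rng_seed=seed)
                    res.ses[(metric, constraint)] = tab
                    vals = tab.loc[tab["defined"], "ses"]
                    if len(vals) >= 3:
                        res.ses_tests[(metric, constraint)] = \
                            nulls_mod.test_ses(vals)

        if run_inference:
            q = alpha[alpha["scale"] == "quadrat"].set_index("unit")
            zone = cm.zone.loc[q.index]
            rp = cm.rockpool_present.loc[q.index]
            for resp, col in (("species_richness", "species_richness"),
                              ("group_richness", "group_richness")):
                fit = inf_mod.fit_glm_quasipoisson(q[col], zone, rp)
                fit.response = resp
                res.anova[resp] = fit
            lm_responses = {"fric_scaled": q["fric_scaled"],
                            "fdis": q["fdis"]}
            if run_nulls:
                for metric in nulls_mod.METRICS:
                    tab = res.ses.get((metric, "none"))
                    if tab is not None:
                        s = tab.set_index("quadrat")["ses"].reindex(q.index)
                        lm_responses[f"ses_{metric}"] = s
            for resp, vals in lm_responses.items():
                fit = inf_mod.fit_lm(vals, zone, rp)
                fit.response = resp
                res.anova[resp] = fit
            res.relationship = inf_mod.richness_fd_relationship(alpha)
        return res
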
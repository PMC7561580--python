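# traitshore

Functional-trait diversity of intertidal seaweed assemblages along the
emersion gradient.

Rocky-shore macroalgae live along one of ecology's steepest stress
gradients: with increasing shore height, emersion time grows and
communities turn over in well-known zones (low, mid, upper shore,
delimited by dominant fucoids and kelp). `traitshore` is for community
ecologists who want to ask what that taxonomic attrition does to
*function*: does trait space contract, shift, or merely thin out as
stress increases, and do water-retaining rock pools buffer the loss?

The package implements the full analysis chain:

- **Trait space** — nine functional markers (STA, SA:V, thickness,
  TDMC, C:N, length, pneumatocysts, branching order, SA:P),
  log-z-scored, combined into a weighted Gower dissimilarity
  d(i,j) = Σₖ wₖ δₖ(i,j)/Σₖ wₖ with block weights that balance
  photosynthesis, structure and space use; principal coordinates with
  Cailliez correction for non-Euclidean matrices.
- **Emergent groups** — PAM k-medoids on the Gower matrix, with k
  chosen as the largest number of groups whose pairwise PERMANOVA
  contrasts are all significant at α = 0.05.
- **α-diversity** — species richness, emergent-group richness,
  convex-hull functional richness FRic scaled to the species pool, and
  abundance-weighted functional dispersion FDis, at quadrat and zone
  scale.
- **β-diversity** — multiple-site Sørensen dissimilarity partitioned
  into turnover (β_SIM) and nestedness (β_SNE = β_SOR − β_SIM), at the
  taxonomic level (incidences) and the functional level (hull volumes
  with exact polytope intersections).
- **Null models** — 999 trait-shuffling randomizations per community,
  standardized effect sizes SES = (obs − null mean)/null sd, optional
  zone-constrained shuffles, one-sample t / Wilcoxon tests.
- **Inference** — quasi-Poisson GLMs (counts) and Gaussian LMs
  (functional metrics, SES) with sequential Zone, RP, Zone × RP F
  tests and compact-letter zone contrasts.
- **Synthetic communities** — a first-class generator producing trait
  tables and zoned, balanced community matrices under known assembly
  processes (random, environmental filtering, limiting similarity,
  nested zonation), so the whole pipeline is testable end to end.

## Worked example

```python
import traitshore as ts

model = ts.FunctionalDiversityModel.from_synthetic(rng_seed=1,
                                                   n_null=999, n_perm=999)
res = model.fit(seed=1, constraints=("none",))
print(res.summary())
```

Abridged output (random assembly, 50 species, 84 quadrats):

```text
Trait space: 50 species, 4 retained axes (29% inertia on the first two), correction: cailliez
Emergent groups: k = 6

Zone-scale alpha diversity (low -> upper):
       species_richness  group_richness  fric_scaled   fdis
low                  50               6          1.0  0.223
mid                  50               6          1.0  0.211
upper                50               6          1.0  0.214

SES vs. null (trait shuffling):
  fric [none]: mean SES = +0.087, wilcoxon test p = 0.993 (n = 84)
  fdis [none]: mean SES = +0.075, wilcoxon test p = 0.755 (n = 84)

Zone x rock-pool models (sequential F tests):
  species_richness [quasipoisson], zone letters {'low': 'c', 'mid': 'b', 'upper': 'a'}
         term        df  deviance  resid_deviance         F         p
         zone         2   79.4135         87.6549   36.7960    0.0000
     rockpool         1    0.1156         87.5394    0.1071    0.7443
zone:rockpool         2    3.0961         84.4433    1.4346    0.2444
```

Reading it: the generator's zone richness targets decline low → upper,
and the quasi-Poisson GLM recovers that as a strong Zone effect with
all three zones separated (letters c/b/a); because assembly was
*random* with respect to traits, every zone still contains all six
emergent groups, the pooled zone hulls fill the trait space
(fric_scaled = 1.0), and the mean SES of both functional metrics sits
near zero with non-significant one-sample tests — the null model
reports, correctly, that nothing beyond richness structures these
communities. Re-running with `AssemblyScenario(process="filtering")`
drives mean SES of FRic strongly negative (trait-space contraction);
`process="limiting_similarity"` pushes mean SES of FDis positive
(over-dispersion).

There is also a CLI for shell use:

```bash
traitshore simulate --process filtering --seed 1 --out data/
traitshore run --traits data/traits.csv --communities data/communities.csv \
               --seed 1 --out results/
```

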
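"""Core data containers for trait-based diversity analysis.

Two tables drive everything downstream: a species x trait matrix with
per-trait metadata (kind, weight, eco-physiological block) and a
quadrat x species percent-cover matrix with per-quadrat metadata
(site, shore zone, rock-pool cover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical trait set: nine functional markers of macroalgal
#: eco-physiology, grouped in three blocks that the weights equalise.
TRAIT_BLOCKS = {
    "sta": "photosynthesis",          # specific thallus area (mm2 g-1)
    "sa_v": "photosynthesis",         # surface area : volume (mm2 mL-1)
    "thickness": "photosynthesis",    # frond thickness (mm)
    "tdmc": "structure",              # thallus dry matter content (ratio)
    "c_n": "structure",               # carbon : nitrogen ratio
    "length": "space_use",            # thallus length (cm)
    "pneumatocysts": "space_use",     # gas bladders present (yes/no)
    "branching_order": "space_use",   # branching order (integer)
    "sa_p": "space_use",              # surface area : perimeter
}

#: Block weights chosen so each of the three eco-physiological aspects
#: contributes equally to the mixed-trait dissimilarity.
TRAIT_WEIGHTS = {
    "sta": 0.33, "sa_v": 0.33, "thickness": 0.33,
    "tdmc": 0.5, "c_n": 0.5,
    "length": 0.25, "pneumatocysts": 0.25,
    "branching_order": 0.25, "sa_p": 0.25,
}

TRAIT_KINDS = {t: ("binary" if t == "pneumatocysts" else "continuous")
               for t in TRAIT_BLOCKS}

TRAIT_NAMES = list(TRAIT_BLOCKS)

ZONES = ("low", "mid", "upper")

#: Zone-defining canopy species: a zone is assigned when its indicators
#: jointly exceed 80% of total macroalgal cover.
ZONE_INDICATORS = {
    "low": ("Laminaria digitata", "Fucus serratus"),
    "mid": ("Ascophyllum nodosum", "Fucus vesiculosus"),
    "upper": ("Pelvetia canaliculata", "Fucus spiralis"),
}

#: Rock pools are treated as a binary habitat: present at >= 5% cover.
ROCKPOOL_THRESHOLD = 5.0


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class TraitTable:
    """Species x trait values with per-trait kind, weight and block.

    Parameters
    ----------
    data : pandas.DataFrame
        Species (index) x trait (columns) values. Continuous traits must
        be strictly positive before log-transformation; the binary
        pneumatocysts trait is coded 0/1; branching order is a
        non-negative integer.
    kinds, weights, blocks : dict, optional
        Per-trait metadata; default to the canonical nine-trait scheme.
    preprocessed : bool
        True once traits have been log-transformed and z-scored
        (after which positivity no longer applies).
    """

    data: pd.DataFrame
    kinds: dict = field(default_factory=lambda: dict(TRAIT_KINDS))
    weights: dict = field(default_factory=lambda: dict(TRAIT_WEIGHTS))
    blocks: dict = field(default_factory=lambda: dict(TRAIT_BLOCKS))
    preprocessed: bool = False

    def __post_init__(self):
        self.validate()

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def continuous_traits(self) -> list:
        return [t for t in self.trait_names if self.kinds[t] == "continuous"]

    def binary_traits(self) -> list:
        return [t for t in self.trait_names if self.kinds[t] == "binary"]

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[t] for t in self.trait_names], float)

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate species ids: {list(dup)}")
        if self.n_species < 3:
            raise ValidationError("a trait table needs at least 3 species")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()]
            raise ValidationError(f"missing trait values in: {list(bad)}")
        missing = set(self.trait_names) - set(self.kinds)
        if missing:
            raise ValidationError(f"traits without a declared kind: {missing}")
        for t in self.trait_names:
            w = self.weights.get(t)
            if w is None or w <= 0:
                raise ValidationError(f"trait {t!r} needs a positive weight")
        for t in self.binary_traits():
            vals = set(np.unique(self.data[t].to_numpy()))
            if not vals <= {0, 1}:
                raise ValidationError(
                    f"binary trait {t!r} must be 0/1, got {sorted(vals)}")
        if not self.preprocessed:
            for t in self.continuous_traits():
                col = self.data[t].to_numpy(float)
                floor = 0.0 if t == "branching_order" else np.nextafter(0, 1)
                if (col < floor).any() or (t != "branching_order"
                                           and (col <= 0).any()):
                    sp = self.data.index[np.asarray(col <= 0)
                                         if t != "branching_order"
                                         else np.asarray(col < 0)][0]
                    raise ValidationError(
                        f"trait {t!r} of species {sp!r} must be "
                        f"{'non-negative' if t == 'branching_order' else 'strictly positive'}")

    def block_weight_sums(self) -> dict:
        out: dict = {}
        for t in self.trait_names:
            out.setdefault(self.blocks[t], 0.0)
            out[self.blocks[t]] += self.weights[t]
        return out

    def to_csv(self, path) -> None:
        self.data.rename_axis("species").to_csv(path)

    def copy(self) -> "TraitTable":
        return TraitTable(self.data.copy(), dict(self.kinds),
                          dict(self.weights), dict(self.blocks),
                          self.preprocessed)


@dataclass
class CommunityMatrix:
    """Quadrat x species percent cover plus quadrat metadata.

    Cover is percent of quadrat area; multi-layered canopies mean row
    totals may legitimately exceed 100.
    """

    cover: pd.DataFrame
    meta: pd.DataFrame  # columns: site, zone, rockpool_cover_pct

    def __post_init__(self):
        self.validate()

    @property
    def quadrat_ids(self) -> list:
        return list(self.cover.index)

    @property
    def species_ids(self) -> list:
        return list(self.cover.columns)

    @property
    def n_quadrats(self) -> int:
        return len(self.cover)

    @property
    def zone(self) -> pd.Series:
        return self.meta["zone"]

    @property
    def rockpool_present(self) -> pd.Series:
        return self.meta["rockpool_cover_pct"] >= ROCKPOOL_THRESHOLD

    def validate(self) -> None:
        if not self.cover.index.equals(self.meta.index):
            raise ValidationError("cover and metadata indices differ")
        if self.cover.index.has_duplicates:
            raise ValidationError("duplicate quadrat ids")
        arr = self.cover.to_numpy(float)
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite cover values")
        if (arr < 0).any():
            raise ValidationError("negative cover values")
        for col in ("site", "zone", "rockpool_cover_pct"):
            if col not in self.meta.columns:
                raise ValidationError(f"metadata column {col!r} missing")
        bad = set(self.meta["zone"]) - set(ZONES)
        if bad:
            raise ValidationError(
                f"unknown zone labels {sorted(bad)}; allowed: {list(ZONES)}")
        if (self.meta["rockpool_cover_pct"].to_numpy(float) < 0).any():
            raise ValidationError("negative rock-pool cover")

    def check_species_covered(self, traits: TraitTable) -> None:
        missing = set(self.species_ids) - set(traits.species_ids)
        if missing:
            raise ValidationError(
                f"species in communities but absent from traits: "
                f"{sorted(missing)}")

    def presence(self) -> pd.DataFrame:
        return self.cover > 0

    def zone_presence(self) -> pd.DataFrame:
        """Zone x species incidence: present in any quadrat of the zone."""
        return (self.cover > 0).groupby(self.meta["zone"]).any().reindex(
            [z for z in ZONES if z in set(self.meta["zone"])])

    def zone_cover(self) -> pd.DataFrame:
        """Zone x species summed cover across the zone's quadrats."""
        return self.cover.groupby(self.meta["zone"]).sum().reindex(
            [z for z in ZONES if z in set(self.meta["zone"])])

    def drop_species(self, species) -> "CommunityMatrix":
        keep = [s for s in self.species_ids if s not in set(species)]
        return CommunityMatrix(self.cover[keep].copy(), self.meta.copy())

    def subset(self, quadrats) -> "CommunityMatrix":
        return CommunityMatrix(self.cover.loc[quadrats].copy(),
                               self.meta.loc[quadrats].copy())

    def to_csv(self, path) -> None:
        wide = self.meta.join(self.cover)
        wide.rename_axis("quadrat").to_csv(path)
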
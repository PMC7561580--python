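"""CSV ingestion with fail-fast validation.

Trait tables are wide (one row per species, the nine canonical trait
columns); community tables are accepted wide (quadrat rows, metadata
columns site/zone/rockpool_cover_pct, then species columns) or long
(quadrat, species, cover, plus metadata), auto-detected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    TRAIT_NAMES,
    ZONES,
    CommunityMatrix,
    TraitTable,
    ValidationError,
)

_META_COLS = ("site", "zone", "rockpool_cover_pct")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        parsed = pd.to_numeric(out[c], errors="coerce")
        bad = parsed.isna() & out[c].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValidationError(
                f"{path}: non-numeric value {out[c][bad].iloc[0]!r} in "
                f"column {c!r} (line {line})")
        if parsed.isna().any():
            line = int(np.flatnonzero(parsed.isna())[0]) + 2
            raise ValidationError(
                f"{path}: missing value in column {c!r} (line {line})")
        out[c] = parsed
    return out


def read_trait_csv(path) -> TraitTable:
    df = pd.read_csv(path, dtype=str)
    if "species" not in df.columns:
        raise ValidationError(f"{path}: first column must be 'species'")
    unknown = set(df.columns) - {"species", *TRAIT_NAMES}
    if unknown:
        raise ValidationError(
            f"{path}: unrecognised trait columns {sorted(unknown)}; "
            f"expected {TRAIT_NAMES}")
    missing = set(TRAIT_NAMES) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing traits {sorted(missing)}")
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        line = int(dup.index[0]) + 2
        raise ValidationError(
            f"{path}: duplicate species {dup.iloc[0]!r} (line {line})")
    df = _numeric(df, TRAIT_NAMES, path)
    bad_bin = ~df["pneumatocysts"].isin([0, 1])
    if bad_bin.any():
        line = int(np.flatnonzero(bad_bin)[0]) + 2
        raise ValidationError(
            f"{path}: pneumatocysts must be 0/1 (line {line})")
    data = df.set_index("species")[TRAIT_NAMES].astype(float)
    data.index.name = None
    return TraitTable(data)


def read_community_csv(path, traits: TraitTable | None = None
                       ) -> CommunityMatrix:
    df = pd.read_csv(path, dtype=str)
    long_format = {"quadrat", "species", "cover"} <= set(df.columns)
    if long_format:
        df = _numeric(df, ["cover", "rockpool_cover_pct"], path)
        wide = df.pivot_table(index="quadrat", columns="species",
                              values="cover", fill_value=0.0, sort=False)
        meta = (df.drop_duplicates("quadrat")
                .set_index("quadrat")[list(_META_COLS)])
        meta = meta.loc[wide.index]
    else:
        if "quadrat" not in df.columns:
            raise ValidationError(f"{path}: 'quadrat' column required")
        miss = set(_META_COLS) - set(df.columns)
        if miss:
            raise ValidationError(f"{path}: metadata columns {sorted(miss)} "
                                  "missing")
        species_cols = [c for c in df.columns
                        if c not in ("quadrat", *_META_COLS)]
        df = _numeric(df, species_cols + ["rockpool_cover_pct"], path)
        wide = df.set_index("quadrat")[species_cols].astype(float)
        meta = df.set_index("quadrat")[list(_META_COLS)]
    bad_zone = set(meta["zone"]) - set(ZONES)
    if bad_zone:
        raise ValidationError(
            f"{path}: unknown zone labels {sorted(bad_zone)}; allowed "
            f"labels are {list(ZONES)}")
    meta = meta.assign(
        rockpool_cover_pct=meta["rockpool_cover_pct"].astype(float))
    wide.index.name = None
    wide.columns.name = None
    meta.index.name = None
    cm = CommunityMatrix(wide, meta)
    if traits is not None:
        cm.check_species_covered(traits)
    return cm
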
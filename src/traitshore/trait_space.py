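"""Weighted Gower dissimilarity and the corrected principal-coordinate
functional space.

The trait space is built in three steps: continuous traits are
log-transformed and z-scored; a weighted Gower dissimilarity mixes the
scaled continuous traits with the binary pneumatocyst trait; principal
coordinates analysis (with a Cailliez correction when the Gower matrix
is non-Euclidean) embeds species in a low-dimensional space on which all
functional-diversity metrics operate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import TraitTable, ValidationError

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with species labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.values, float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.labels) != D.shape[0]:
            raise ValidationError("labels do not match matrix size")
        if not np.isfinite(D).all():
            raise ValidationError("non-finite dissimilarities")
        if np.abs(D - D.T).max() > 1e-12:
            raise ValidationError("matrix not symmetric")
        if np.abs(np.diag(D)).max() > 1e-12:
            raise ValidationError("non-zero diagonal")
        self.values = (D + D.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().rename_axis("species").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(float))


@dataclass
class FunctionalSpace:
    """Species coordinates on retained PCoA axes.

    coordinates are scaled eigenvectors sorted by descending eigenvalue;
    `quality` is the mean squared deviation between the original
    dissimilarities and the Euclidean distances in the retained space.
    """

    labels: list
    coordinates: np.ndarray            # species x m retained axes
    eigenvalues: np.ndarray            # all positive eigenvalues, descending
    inertia_explained: np.ndarray      # fraction per retained axis
    correction_method: str             # "none applied", "cailliez", "sqrt"
    quality: float
    source_distance: DistanceMatrix | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return self.coordinates.shape[1]

    def coords_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.labels,
            columns=[f"pco{i + 1}" for i in range(self.m)])

    def coords_for(self, species) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.labels)}
        return self.coordinates[[pos[s] for s in species]]

    def to_files(self, csv_path, json_path) -> None:
        self.coords_df().rename_axis("species").to_csv(csv_path)
        with open(json_path, "w") as fh:
            json.dump({"eigenvalues": list(map(float, self.eigenvalues)),
                       "inertia_explained":
                           list(map(float, self.inertia_explained)),
                       "correction_method": self.correction_method,
                       "quality": float(self.quality)}, fh, indent=2)


# ---------------------------------------------------------------------------
# preprocessing and Gower dissimilarity

def preprocess_traits(tt: TraitTable) -> TraitTable:
    """Log-transform and z-score continuous traits; leave binaries alone.

    Branching order, which can be zero for unbranched thalli, uses
    log(x+1); every other continuous trait uses the natural log. A
    constant column cannot be scaled and raises.
    """
    if tt.preprocessed:
        return tt
    out = tt.data.copy().astype(float)
    for t in tt.continuous_traits():
        col = out[t].to_numpy(float)
        if t == "branching_order":
            logged = np.log1p(col)
        else:
            if (col <= 0).any():
                sp = out.index[col <= 0][0]
                raise ValidationError(
                    f"trait {t!r} of species {sp!r} is not strictly "
                    "positive; log-transform undefined")
            logged = np.log(col)
        sd = logged.std(ddof=1)
        if sd == 0:
            raise ValidationError(
                f"trait {t!r} is constant; z-scoring undefined")
        out[t] = (logged - logged.mean()) / sd
    return TraitTable(out, dict(tt.kinds), dict(tt.weights),
                      dict(tt.blocks), preprocessed=True)


def gower_distance(tt: TraitTable) -> DistanceMatrix:
    """Weighted Gower dissimilarity over mixed traits.

    d(i,j) = sum_k w_k * delta_k(i,j) / sum_k w_k with
    delta_k = |x_ik - x_jk| / range_k for continuous traits (range taken
    over all species) and delta_k = |x_ik - x_jk| in {0,1} for binary
    traits. Result in [0,1]. A zero-range trait contributes 0 (warned).
    """
    n = tt.n_species
    w = tt.weight_vector()
    num = np.zeros((n, n))
    wsum = 0.0
    for k, t in enumerate(tt.trait_names):
        col = tt.data[t].to_numpy(float)
        diff = np.abs(col[:, None] - col[None, :])
        wsum += w[k]
        if tt.kinds[t] == "continuous":
            rng = col.max() - col.min()
            if rng == 0:
                warnings.warn(f"trait {t!r} has zero range; it contributes "
                              "nothing to the Gower dissimilarity")
                continue
            diff = diff / rng
        num += w[k] * diff
    if wsum == 0:
        raise ValidationError("all traits degenerate; Gower undefined")
    D = num / wsum
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(tt.species_ids, D)


# ---------------------------------------------------------------------------
# principal coordinates

_NEG_TOL = 1e-8


def _double_center(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D + c (off-diagonal) Euclidean.

    Largest real eigenvalue of the 2n x 2n block matrix
    [[0, 2*Delta1], [-I, -4*Delta2]] with Delta1 = centred(-D^2/2) and
    Delta2 = centred(-D/2).
    """
    n = D.shape[0]
    d1 = _double_center(D ** 2)
    d2 = _double_center(D)  # equals centred(-D/2) * ... see below
    # _double_center applies -1/2 to its argument's outer product form;
    # Delta2 must be centred(-D/2), i.e. _double_center applied to D
    # without squaring already gives -1/2 J D J.
    top = np.hstack([np.zeros((n, n)), 2.0 * d1])
    bot = np.hstack([-np.eye(n), -4.0 * d2])
    eig = np.linalg.eigvals(np.vstack([top, bot]))
    return float(np.max(eig.real))


def pcoa(D: DistanceMatrix, correction: str = "cailliez") -> FunctionalSpace:
    """Principal coordinates of a dissimilarity matrix.

    Double-centres -D^2/2 and eigendecomposes. If negative eigenvalues
    beyond tolerance appear, applies the requested correction (default
    Cailliez: add a constant to off-diagonal dissimilarities making the
    configuration Euclidean; "sqrt": element-wise square root) and
    recomputes. Retains all positive axes; `select_axes` trims.
    """
    if D.n < 3:
        raise ValidationError("PCoA needs at least 3 objects")
    if correction not in ("none", "cailliez", "sqrt"):
        raise ValidationError(f"unknown correction {correction!r}")

    def decompose(mat):
        B = _double_center(mat ** 2)
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        return w[order], V[:, order]

    Dw = D.values
    w, V = decompose(Dw)
    applied = "none applied"
    if w.min() < -_NEG_TOL * max(1.0, abs(w).max()) and correction != "none":
        if correction == "cailliez":
            c = _cailliez_constant(Dw)
            Dw = Dw + c
            np.fill_diagonal(Dw, 0.0)
        else:
            Dw = np.sqrt(Dw)
        w, V = decompose(Dw)
        applied = correction

    pos = w > _NEG_TOL * max(1.0, abs(w).max())
    lam = w[pos]
    coords = V[:, pos] * np.sqrt(lam)
    inertia = lam / lam.sum()
    fs = FunctionalSpace(list(D.labels), coords, lam, inertia, applied,
                         quality=np.nan, source_distance=D)
    fs.quality = representation_quality(fs, fs.m)
    return fs


def representation_quality(fs: FunctionalSpace, m: int) -> float:
    """Mean squared deviation between source dissimilarities and the
    Euclidean distances among the first m coordinates."""
    if fs.source_distance is None:
        return np.nan
    d_m = squareform(pdist(fs.coordinates[:, :m]))
    diff = fs.source_distance.values - d_m
    n = fs.source_distance.n
    iu = np.triu_indices(n, 1)
    return float(np.mean(diff[iu] ** 2))


def select_axes(fs: FunctionalSpace, m: int | None = 4,
                quality_rule: bool = False,
                m_range=range(2, 7)) -> FunctionalSpace:
    """Trim the space to m axes, or pick m by representation quality.

    With ``quality_rule`` the m in ``m_range`` minimising the mean
    squared deviation between original and embedded distances is kept
    (ties to the smaller m). A fixed m larger than the number of
    positive axes is capped with a warning.
    """
    avail = fs.coordinates.shape[1]
    if quality_rule:
        cands = [mm for mm in m_range if mm <= avail] or [avail]
        quals = [representation_quality(fs, mm) for mm in cands]
        m = cands[int(np.argmin(np.round(quals, 12)))]
    else:
        if m is None or m < 2:
            raise ValidationError("m must be >= 2 (or use quality_rule)")
        if m > avail:
            warnings.warn(f"requested {m} axes but only {avail} positive "
                          "axes available; capping")
            m = avail
    out = FunctionalSpace(fs.labels, fs.coordinates[:, :m].copy(),
                          fs.eigenvalues, fs.inertia_explained[:m],
                          fs.correction_method,
                          quality=representation_quality(fs, m),
                          source_distance=fs.source_distance)
    return out


def fix_axis_signs(fs: FunctionalSpace, tt: TraitTable) -> FunctionalSpace:
    """Deterministic axis orientation: flip each axis so the trait with
    the largest absolute correlation loads positively."""
    X = tt.data.to_numpy(float)
    coords = fs.coordinates.copy()
    for a in range(fs.m):
        r = np.array([_pearson(X[:, j], coords[:, a])
                      for j in range(X.shape[1])])
        j = int(np.nanargmax(np.abs(r)))
        if r[j] < 0:
            coords[:, a] = -coords[:, a]
    return FunctionalSpace(fs.labels, coords, fs.eigenvalues,
                           fs.inertia_explained, fs.correction_method,
                           fs.quality, fs.source_distance)


def _pearson(x, y) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def trait_axis_correlations(tt: TraitTable,
                            fs: FunctionalSpace) -> pd.DataFrame:
    """Pearson correlation of each (preprocessed) trait with each
    retained axis — the arrow table of a PCoA biplot."""
    rows = []
    coords = fs.coords_for(tt.species_ids)
    for t in tt.trait_names:
        x = tt.data[t].to_numpy(float)
        for a in range(fs.m):
            rows.append({"trait": t, "axis": a + 1,
                         "r": _pearson(x, coords[:, a])})
    return pd.DataFrame(rows)


def build_functional_space(tt: TraitTable, m: int | None = 4,
                           quality_rule: bool = False,
                           correction: str = "cailliez") -> FunctionalSpace:
    """Pipeline helper: preprocess -> Gower -> PCoA -> trim -> orient."""
    pre = preprocess_traits(tt)
    D = gower_distance(pre)
    fs = select_axes(pcoa(D, correction=correction), m=m,
                     quality_rule=quality_rule)
    return fix_axis_signs(fs, pre)
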
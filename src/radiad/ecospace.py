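"""Phylogeny-corrected multidimensional ecospace.

Builds a Gower dissimilarity matrix over mixed traits (continuous ln
body mass, categorical diet and activity pattern), removes the component
explained by phylogenetic distance via a matrix regression on the lower
triangle, embeds the residual dissimilarities in two dimensions with
non-metric multidimensional scaling (NMDS), and quantifies occupied
niche breadth as convex-hull areas of species groups — in particular the
contraction of the ecospace after extinctions (area of extant species
over area of all species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "gower_matrix",
    "phylo_residual",
    "EcospaceEmbedding",
    "nmds_embed",
    "hull_areas",
    "ecospace_pipeline",
]


def gower_matrix(
    data: pd.DataFrame,
    continuous: tuple = ("ln_mass_g",),
    categorical: tuple = ("diet", "activity"),
) -> pd.DataFrame:
    """Gower dissimilarity over mixed variables.

    Per variable: continuous |x_i - x_j| / range, categorical 0/1
    mismatch; the coefficient is the unweighted mean over variables.
    Continuous variables with zero range are dropped with a warning.
    """
    import warnings

    cols_c = [c for c in continuous if c in data.columns]
    cols_k = [c for c in categorical if c in data.columns]
    if not cols_c and not cols_k:
        raise ValueError("no declared variables found in the data")
    n = len(data)
    parts = []
    for c in cols_c:
        x = data[c].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"missing values in continuous variable {c!r}")
        rng = np.ptp(x)
        if rng == 0:
            warnings.warn(f"zero range in {c!r}; variable dropped")
            continue
        parts.append(np.abs(x[:, None] - x[None, :]) / rng)
    for c in cols_k:
        x = data[c].to_numpy()
        parts.append((x[:, None] != x[None, :]).astype(float))
    if not parts:
        raise ValueError("all variables degenerate")
    D = np.mean(parts, axis=0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=data.index, columns=data.index)


def phylo_residual(d_trait: pd.DataFrame, d_phylo: pd.DataFrame) -> pd.DataFrame:
    """Residual trait dissimilarity after an OLS matrix regression
    (intercept + slope) of the lower triangle on phylogenetic distance,
    refolded into a symmetric zero-diagonal matrix."""
    if list(d_trait.index) != list(d_phylo.index):
        common = d_trait.index.intersection(d_phylo.index)
        if len(common) < 3:
            raise ValueError("fewer than 3 shared species")
        d_trait = d_trait.loc[common, common]
        d_phylo = d_phylo.loc[common, common]
    Dt = d_trait.to_numpy(dtype=float)
    Dp = d_phylo.to_numpy(dtype=float)
    iu = np.tril_indices_from(Dt, k=-1)
    x, y = Dp[iu], Dt[iu]
    if np.ptp(x) == 0:
        raise ValueError("constant phylogenetic distances; regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    R = np.zeros_like(Dt)
    R[iu] = resid
    R = R + R.T
    return pd.DataFrame(R, index=d_trait.index, columns=d_trait.columns)


@dataclass
class EcospaceEmbedding:
    coords: pd.DataFrame  # species x (MDS1, MDS2, ...)
    stress: float  # Kruskal stress-1
    k: int
    hulls: dict = field(default_factory=dict)  # group -> {"area", "n", ...}

    def to_dict(self):
        hulls = {}
        for g, h in self.hulls.items():
            if isinstance(h, dict):
                hulls[g] = {
                    kk: (vv if isinstance(vv, (int, bool)) else float(vv))
                    for kk, vv in h.items()
                }
            else:
                hulls[g] = float(h)
        return {"stress": float(self.stress), "k": self.k, "hulls": hulls}


def _kruskal_stress1(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) regression of the
    embedding distances on the input dissimilarity ranks."""
    iu = np.triu_indices_from(D, k=1)
    d_in = D[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    d_emb = np.sqrt((diff ** 2).sum(-1))[iu]
    order = np.argsort(d_in, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat_sorted = iso.fit_transform(np.arange(len(d_in)), d_emb[order])
    dhat = np.empty_like(d_emb)
    dhat[order] = dhat_sorted
    denom = float(np.sum(d_emb ** 2))
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((d_emb - dhat) ** 2) / denom))


def nmds_embed(
    D: pd.DataFrame,
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    max_iter: int = 300,
) -> EcospaceEmbedding:
    """Non-metric MDS embedding of a symmetric dissimilarity matrix.

    Residual (possibly negative) dissimilarities are shifted by their
    minimum — a rank-preserving transform, so the non-metric embedding
    is unaffected.  The best of ``n_starts`` random initializations is
    kept; the reported stress is Kruskal stress-1.
    """
    A = D.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("D must be a symmetric square matrix")
    A = A.copy()
    mn = A.min()
    if mn < 0:
        A = A - mn
        np.fill_diagonal(A, 0.0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        mds = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_starts,
            max_iter=max_iter,
            eps=1e-6,
            random_state=None if seed is None else int(seed) % (2**32),
            normalized_stress=True,
        )
        coords = mds.fit_transform(A)
    coords = coords - coords.mean(axis=0)
    stress = _kruskal_stress1(A, coords)
    cols = [f"MDS{i+1}" for i in range(k)]
    return EcospaceEmbedding(
        coords=pd.DataFrame(coords, index=D.index, columns=cols),
        stress=stress, k=k,
    )


def _hull_area(points: np.ndarray) -> tuple[float, bool]:
    """Planar convex-hull area; (0, flagged) for <3 or collinear points."""
    if len(points) < 3:
        return 0.0, True
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, True  # collinear / degenerate
    return float(hull.volume), False  # in 2-D, .volume is the area


def hull_areas(
    embedding: EcospaceEmbedding | pd.DataFrame,
    groups: dict,
) -> dict:
    """Convex-hull areas for species groups plus the extant/all
    contraction ratio (when groups named ``"extant"`` and ``"all"`` are
    provided).  A subset group's hull never exceeds its superset's."""
    coords = embedding.coords if isinstance(embedding, EcospaceEmbedding) else embedding
    out = {}
    for name, members in groups.items():
        members = [m for m in members if m in coords.index]
        pts = coords.loc[members].to_numpy()[:, :2]
        area, flagged = _hull_area(pts)
        out[name] = {"area": area, "n": len(members), "degenerate": flagged}
    if "extant" in out and "all" in out and out["all"]["area"] > 0:
        out["contraction_ratio"] = out["extant"]["area"] / out["all"]["area"]
    if isinstance(embedding, EcospaceEmbedding):
        embedding.hulls = out
    return out


def ecospace_pipeline(
    species: pd.DataFrame,
    d_phylo: pd.DataFrame,
    extinct_col: str = "extinct",
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = None,
    groups: dict | None = None,
) -> EcospaceEmbedding:
    """Full ecospace construction from a species table.

    ``species`` needs columns ``ln_mass_g``, ``diet``, ``activity`` and
    an 0/1 ``extinct`` flag; ``d_phylo`` is the patristic distance
    matrix.  Returns the embedding with hull areas for extant species,
    all species, and any extra ``groups``.
    """
    d_trait = gower_matrix(species)
    resid = phylo_residual(d_trait, d_phylo)
    emb = nmds_embed(resid, k=k, n_starts=n_starts, seed=seed)
    g = {
        "all": list(species.index),
        "extant": list(species.index[species[extinct_col] == 0]),
    }
    if groups:
        g.update(groups)
    hull_areas(emb, g)
    return emb
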
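"""GGE biplot analysis of a genotype × environment table.

The GGE model keeps genotype main effects together with the
genotype × environment interaction and removes only the environment main
effect: the table is column-centered (per tissue) and the centered matrix is
decomposed by SVD,

    y_ge − μ − β_e = Σ_n λ_n γ_gn δ_en .

The first two axes give the biplot.  How the singular values are split
between the genotype and environment coordinates is the singular value
partitioning (SVP): genotype-focused (``γ·λ``, ``δ``), environment-focused
(``γ``, ``δ·λ``) or symmetric (``γ·√λ``, ``δ·√λ``).

Four standard interpretive views are derived from the fitted coordinates:

* **tissue relationships** — cosines of angles between environment vectors
  approximate the genotype-wise correlations between environments, and the
  vector length measures an environment's discriminating ability;
* **which-won-where** — the convex-hull polygon of genotype points with
  sector rays perpendicular to its edges; the hull vertex of a sector has
  the highest (rank-2) expression in every environment falling in it;
* **mean vs stability** — projections on the average-environment axis (ATA)
  rank mean performance, perpendicular deviations rank instability;
* **ideal-genotype distance** — Euclidean distance to a hypothetical point
  on the ATA with the length of the longest genotype vector; small distance
  means both high and stable expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ammi import GEMatrix

__all__ = ["GGEBiplot", "SectorPartition", "StabilityRanking",
           "gge_decompose", "tissue_relationships", "which_won_where",
           "mean_stability", "ideal_gene_distance"]

_SVP_EXPONENT = {"genotype": 1.0, "environment": 0.0, "symmetric": 0.5}


@dataclass
class SectorPartition:
    """Which-won-where view: hull, sector rays and per-tissue winners."""

    hull: list                 # hull-vertex gene labels, counterclockwise
    rays: np.ndarray           # sector boundary angles (radians), sorted
    winners: dict              # tissue -> winning gene
    regions: dict              # winning gene -> list of tissues

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, w) for t, w in self.winners.items()],
            columns=["tissue", "winner"])


@dataclass
class StabilityRanking:
    """Mean-performance, stability and ideal-distance scores and orders."""

    mean_scores: dict
    stability_scores: dict
    ideal_distances: dict
    mean_order: list           # genes, highest mean first
    stability_order: list      # genes, most stable first
    comprehensive_order: list  # genes, closest to ideal first

    @property
    def frame(self) -> pd.DataFrame:
        genes = list(self.mean_scores)
        return pd.DataFrame({
            "gene": genes,
            "mean_score": [self.mean_scores[g] for g in genes],
            "stability_score": [self.stability_scores[g] for g in genes],
            "ideal_distance": [self.ideal_distances.get(g, np.nan)
                               for g in genes],
        })


class GGEBiplot:
    """Tissue-centered SVD biplot of a gene × tissue table.

    Parameters
    ----------
    scale : bool, default False
        Divide each centered column by its sample SD before the SVD
        (correlation-like biplot).  The default keeps raw fold-change scale.
    svp : {"symmetric", "genotype", "environment"}, default "symmetric"
        Singular value partitioning between gene and tissue coordinates.
    n_components : int, default 2
        Axes kept in the biplot coordinates (views need 2).

    Attributes
    ----------
    gene_coords_, tissue_coords_ : ndarray, (g, n_components), (e, n_components)
        Biplot coordinates under the chosen SVP.
    singular_values_ : ndarray
        All min(g, e) singular values of the centered matrix, descending.
    pct_variance_ : ndarray
        Percent of G+GE SS captured per axis (all axes).
    full_gene_scores_, full_tissue_scores_ : ndarray
        Unscaled orthonormal γ and δ for every axis (used for full-rank
        checks such as cosine ≙ correlation).
    """

    def __init__(self, scale: bool = False, svp: str = "symmetric",
                 n_components: int = 2):
        self.scale = scale
        self.svp = svp
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"scale": self.scale, "svp": self.svp,
                "n_components": self.n_components}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X):
        """Fit on a :class:`GEMatrix`, DataFrame or 2-D array of means."""
        if self.svp not in _SVP_EXPONENT:
            raise ValueError(f"svp must be one of {sorted(_SVP_EXPONENT)}")
        if isinstance(X, GEMatrix):
            y, genes, tissues = X.means, X.genes, X.tissues
        elif isinstance(X, pd.DataFrame):
            y, genes, tissues = X.to_numpy(dtype=float), list(X.index), \
                list(X.columns)
        else:
            y = np.asarray(X, dtype=float)
            genes = list(range(y.shape[0]))
            tissues = list(range(y.shape[1]))
        g, e = y.shape
        if g < 3:
            raise ValueError("2-PC biplot views need at least 3 genes")
        z = y - y.mean(axis=0, keepdims=True)
        if self.scale:
            sd = y.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("cannot scale: zero-variance tissue column")
            z = z / sd
        if not np.any(z):
            raise ValueError("degenerate input: no gene variation after "
                             "tissue centering")
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        k = int(self.n_components)
        if not 2 <= k <= len(s):
            raise ValueError(f"n_components must be in [2, {len(s)}]")
        # orient each axis so the average tissue loading is non-negative
        for n in range(len(s)):
            if vt[n, :].sum() < 0:
                u[:, n] *= -1
                vt[n, :] *= -1
        f = _SVP_EXPONENT[self.svp]
        self.genes_, self.tissues_ = genes, tissues
        self.centered_ = z
        self.singular_values_ = s
        self.full_gene_scores_ = u
        self.full_tissue_scores_ = vt.T
        self.pct_variance_ = 100.0 * s ** 2 / (s ** 2).sum()
        self.gene_coords_ = u[:, :k] * s[:k] ** f
        self.tissue_coords_ = vt[:k, :].T * s[:k] ** (1 - f)
        return self

    # -- views --------------------------------------------------------------
    def tissue_relationships(self, full_rank: bool = False):
        """Cosine matrix, vector lengths and discrimination ranking.

        With ``full_rank=True`` the environment-focused coordinates of all
        axes are used, in which the cosine between two tissue vectors equals
        the gene-wise Pearson correlation of the two centered columns.
        Otherwise the fitted (truncated) tissue coordinates are used, which
        is what the drawn biplot shows.
        """
        if full_rank:
            coords = self.full_tissue_scores_ * self.singular_values_
        else:
            if self.svp == "genotype":
                raise ValueError("tissue relationships need environment- or "
                                 "symmetric-SVP coordinates")
            coords = self.tissue_coords_
        lengths = np.linalg.norm(coords, axis=1)
        cos = np.full((len(lengths), len(lengths)), np.nan)
        nz = lengths > 0
        denom = np.outer(lengths, lengths)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(np.outer(nz, nz), (coords @ coords.T) / denom,
                           np.nan)
        order = [self.tissues_[i] for i in np.argsort(-lengths)]
        cos_df = pd.DataFrame(cos, index=self.tissues_, columns=self.tissues_)
        len_s = pd.Series(lengths, index=self.tissues_, name="length")
        return cos_df, len_s, order

    def which_won_where(self) -> SectorPartition:
        """Convex-hull polygon view: sector winners per tissue.

        Sector boundaries are rays from the origin perpendicular to the
        hull edges; the winner of a sector is its hull vertex, equivalently
        the gene maximising the inner product with the tissue vector.  Ties
        go to the gene with the larger PC1 projection.
        """
        from scipy.spatial import ConvexHull, QhullError

        G = self.gene_coords_[:, :2]
        E = self.tissue_coords_[:, :2]
        spread = np.linalg.svd(G - G.mean(axis=0), compute_uv=False)
        if spread[1] <= 1e-6 * spread[0]:
            raise ValueError("gene points are collinear; the polygon view "
                             "is degenerate")
        try:
            hull = ConvexHull(G)
        except QhullError as exc:
            raise ValueError("gene points are collinear; the polygon view "
                             "is degenerate") from exc
        hv = list(hull.vertices)  # counterclockwise
        # rays perpendicular to each hull edge
        rays = []
        for a, b in zip(hv, hv[1:] + hv[:1]):
            edge = G[b] - G[a]
            normal = np.array([edge[1], -edge[0]])  # outward for ccw hull
            rays.append(np.arctan2(normal[1], normal[0]))
        winners, regions = {}, {}
        for j, t in enumerate(self.tissues_):
            proj = G[hv] @ E[j]
            best = np.flatnonzero(proj == proj.max())
            if len(best) > 1:  # deterministic tie-break on PC1 projection
                best = [best[int(np.argmax(G[[hv[i] for i in best], 0]))]]
            w = self.genes_[hv[int(best[0])]]
            winners[t] = w
            regions.setdefault(w, []).append(t)
        return SectorPartition(hull=[self.genes_[i] for i in hv],
                               rays=np.sort(np.array(rays)),
                               winners=winners, regions=regions)

    def _ata(self) -> np.ndarray:
        if self.svp == "environment":
            raise ValueError("mean/stability views need genotype- or "
                             "symmetric-SVP coordinates")
        mean_vec = self.tissue_coords_[:, :2].mean(axis=0)
        norm = np.linalg.norm(mean_vec)
        if norm <= 1e-12 * np.abs(self.tissue_coords_).max():
            raise ValueError("average-tissue vector is ~0; no meaningful "
                             "average-tissue axis")
        return mean_vec / norm

    def mean_stability(self) -> StabilityRanking:
        """Mean-performance and stability scores along the ATA."""
        ata = self._ata()
        G = self.gene_coords_[:, :2]
        mean_sc = G @ ata
        perp = G - np.outer(mean_sc, ata)
        stab = np.linalg.norm(perp, axis=1)
        mean_order = [self.genes_[i] for i in np.argsort(-mean_sc)]
        stab_order = [self.genes_[i] for i in np.argsort(stab)]
        return StabilityRanking(
            mean_scores=dict(zip(self.genes_, mean_sc)),
            stability_scores=dict(zip(self.genes_, stab)),
            ideal_distances={},
            mean_order=mean_order, stability_order=stab_order,
            comprehensive_order=[])

    def ideal_gene_distance(self, ideal: str = "vector_length",
                            ) -> StabilityRanking:
        """Distances to the ideal gene and the comprehensive ranking.

        The ideal gene sits on the average-tissue axis with zero
        instability; its length is the longest gene-vector length
        (``ideal="vector_length"``, the conventional definition) or the
        largest mean-performance projection (``ideal="mean_projection"``).
        """
        rank = self.mean_stability()
        ata = self._ata()
        G = self.gene_coords_[:, :2]
        if ideal == "vector_length":
            radius = np.linalg.norm(G, axis=1).max()
        elif ideal == "mean_projection":
            radius = max(rank.mean_scores.values())
        else:
            raise ValueError("ideal must be 'vector_length' or "
                             "'mean_projection'")
        point = ata * radius
        dist = np.linalg.norm(G - point, axis=1)
        rank.ideal_distances = dict(zip(self.genes_, dist))
        rank.comprehensive_order = [self.genes_[i] for i in np.argsort(dist)]
        return rank

    def coordinates(self) -> pd.DataFrame:
        """Biplot coordinates in long form (entity, type, PC1, PC2, ...)."""
        recs = []
        for i, g in enumerate(self.genes_):
            recs.append(["gene", g] + list(self.gene_coords_[i]))
        for j, t in enumerate(self.tissues_):
            recs.append(["tissue", t] + list(self.tissue_coords_[j]))
        cols = ["type", "name"] + [f"PC{n + 1}" for n in
                                   range(self.gene_coords_.shape[1])]
        return pd.DataFrame(recs, columns=cols)


# -- functional wrappers ----------------------------------------------------

def gge_decompose(m, scale: bool = False, svp: str = "symmetric",
                  n_components: int = 2) -> GGEBiplot:
    """Fit a :class:`GGEBiplot` and return the fitted model."""
    return GGEBiplot(scale=scale, svp=svp, n_components=n_components).fit(m)


def tissue_relationships(model: GGEBiplot, full_rank: bool = False):
    return model.tissue_relationships(full_rank=full_rank)


def which_won_where(model: GGEBiplot) -> SectorPartition:
    return model.which_won_where()


def mean_stability(model: GGEBiplot) -> StabilityRanking:
    return model.mean_stability()


def ideal_gene_distance(model: GGEBiplot, **kw) -> StabilityRanking:
    return model.ideal_gene_distance(**kw)
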
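"""Additive Main effects and Multiplicative Interaction (AMMI) analysis.

AMMI models a genotype × environment two-way table of cell means as

    y_ge = μ + α_g + β_e + Σ_n λ_n γ_gn δ_en + θ_ge

where μ is the grand mean, α_g and β_e are zero-sum genotype and environment
main effects, and the multiplicative terms are the SVD of the
double-centered interaction residual: λ_n the nth singular value, γ_gn and
δ_en orthonormal genotype and environment scores of the nth interaction
principal component axis (IPCA).  Here genotypes are genes and environments
are tissues, but nothing in the code depends on that reading.

With r replicates per cell the SS of the nth axis is ``r·λ_n²``; each
retained axis is F-tested against the pooled within-cell error mean square
on Gollob degrees of freedom ``g + e − 1 − 2n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import error_ss_from_sd, f_test
from .io import validate_summary_table

__all__ = ["GEMatrix", "build_ge_matrix", "double_center", "AMMI",
           "ammi_fit", "gollob_df"]


@dataclass
class GEMatrix:
    """A genotype × environment table of cell means plus error information.

    ``means[i, j]`` is the mean response of genotype ``genes[i]`` in
    environment ``tissues[j]``, averaged over ``reps`` replicates.
    ``error_ms``/``error_df`` describe the pooled within-cell error stratum
    used as the F-test denominator; they may be absent (``None``/0) when
    only the decomposition itself is wanted.
    """

    genes: list
    tissues: list
    means: np.ndarray
    reps: int = 1
    error_ms: float | None = None
    error_df: int = 0

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        g, e = self.means.shape
        if g < 2 or e < 2:
            raise ValueError("need at least 2 genotypes and 2 environments")
        if len(self.genes) != g or len(self.tissues) != e:
            raise ValueError("label lengths do not match the mean matrix")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("mean matrix has non-finite entries")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genes,
                            columns=self.tissues)


def build_ge_matrix(summary: pd.DataFrame, condition) -> GEMatrix:
    """Assemble the gene × tissue mean matrix for one condition.

    Cell means come straight from the summary table; the pooled error is
    reconstructed from the per-cell SDs as ``Σ (n−1)·sd²`` with
    ``Σ (n−1)`` degrees of freedom.
    """
    validate_summary_table(summary)
    sub = summary[summary["condition"] == condition]
    if not len(sub):
        raise ValueError(f"no cells for condition {condition!r}")
    genes = sorted(sub["gene"].unique())
    tissues = sorted(sub["tissue"].unique())
    piv = sub.pivot(index="gene", columns="tissue", values="mean")
    if piv.isna().any().any():
        missing = [(g, t) for g in genes for t in tissues
                   if pd.isna(piv.loc[g, t])]
        raise ValueError(f"missing cells for condition {condition!r}: "
                         f"{missing[:5]}")
    reps = sub["n"].unique()
    if len(reps) != 1:
        raise ValueError("replicate count differs between cells")
    ss, df = error_ss_from_sd(sub)
    return GEMatrix(genes=genes, tissues=tissues,
                    means=piv.loc[genes, tissues].to_numpy(),
                    reps=int(reps[0]),
                    error_ms=ss / df if df > 0 else None, error_df=df)


def double_center(means: np.ndarray) -> np.ndarray:
    """Remove row and column means: the interaction residual of the table.

    ``out[g, e] = y[g, e] − rowmean_g − colmean_e + grand``; rows and
    columns of the result each sum to zero.
    """
    y = np.asarray(means, dtype=float)
    return (y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
            + y.mean())


def gollob_df(g: int, e: int, n: int) -> int:
    """Gollob degrees of freedom of the nth IPCA: g + e − 1 − 2n."""
    return g + e - 1 - 2 * n


class AMMI:
    """AMMI decomposition of a genotype × environment table.

    Parameters
    ----------
    n_components : int, default 2
        Number of IPCA axes reported individually in the ANOVA table;
        remaining axes are pooled into the ``Residual`` row.  All
        ``min(g−1, e−1)`` axes are always computed and stored.

    Attributes
    ----------
    grand_mean_ : float
    gene_effects_, tissue_effects_ : ndarray
        Zero-sum additive main effects α_g and β_e.
    singular_values_ : ndarray
        λ_n, descending; IPCA_n SS = reps · λ_n².
    gene_scores_, tissue_scores_ : ndarray
        Orthonormal score matrices γ (g × N) and δ (e × N).  Each axis'
        sign is fixed so the score of the genotype with the largest main
        effect is non-negative.
    anova_table_ : pandas.DataFrame
        Rows Total / Treatment / Gene / Tissue / Interaction / IPCA1.. /
        Residual / Error with df, ss, ms, f, p and pct_total columns.
    pct_of_total_ : dict
        Percent of total SS (treatment + error) per source.
    pct_of_interaction_ : dict
        Percent of interaction SS per IPCA axis (all N axes; sums to 100).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"n_components": self.n_components}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "n_components":
                raise ValueError(f"unknown parameter {k!r}")
            self.n_components = v
        return self

    # -- fitting ------------------------------------------------------------
    def fit(self, X):
        """Fit the decomposition.

        ``X`` may be a :class:`GEMatrix` (enabling F-tests against its
        pooled error) or a plain 2-D array / DataFrame of cell means.
        """
        if isinstance(X, GEMatrix):
            m = X
        elif isinstance(X, pd.DataFrame):
            m = GEMatrix(genes=list(X.index), tissues=list(X.columns),
                         means=X.to_numpy())
        else:
            arr = np.asarray(X, dtype=float)
            m = GEMatrix(genes=list(range(arr.shape[0])),
                         tissues=list(range(arr.shape[1])), means=arr)
        y = m.means
        g, e = y.shape
        r = m.reps
        N = min(g - 1, e - 1)
        k = int(self.n_components)
        if not 1 <= k <= N:
            raise ValueError(f"n_components must be in [1, {N}]")

        self.genes_, self.tissues_, self.reps_ = m.genes, m.tissues, r
        self.grand_mean_ = float(y.mean())
        self.gene_effects_ = y.mean(axis=1) - self.grand_mean_
        self.tissue_effects_ = y.mean(axis=0) - self.grand_mean_
        z = double_center(y)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        u, s, vt = u[:, :N], s[:N], vt[:N, :]
        # sign convention: top-main-effect genotype scores non-negative
        lead = int(np.argmax(self.gene_effects_))
        for n in range(N):
            if u[lead, n] < 0:
                u[:, n] *= -1
                vt[n, :] *= -1
        self.singular_values_ = s
        self.gene_scores_ = u
        self.tissue_scores_ = vt.T
        self.residual_ = z - (u[:, :k] * s[:k]) @ vt[:k, :]

        ss_gene = r * e * float((self.gene_effects_ ** 2).sum())
        ss_tissue = r * g * float((self.tissue_effects_ ** 2).sum())
        ss_int = r * float((z ** 2).sum())
        ss_axes = r * s ** 2
        ss_trt = ss_gene + ss_tissue + ss_int
        err_ms, err_df = m.error_ms, m.error_df
        ss_err = err_ms * err_df if err_ms is not None else 0.0
        ss_tot = ss_trt + ss_err

        rows = [("Total", (g * e * r - 1) if err_ms is not None
                 else g * e - 1, ss_tot),
                ("Treatment", g * e - 1, ss_trt),
                ("Gene", g - 1, ss_gene),
                ("Tissue", e - 1, ss_tissue),
                ("Interaction", (g - 1) * (e - 1), ss_int)]
        for n in range(k):
            rows.append((f"IPCA{n + 1}", gollob_df(g, e, n + 1),
                         float(ss_axes[n])))
        resid_df = (g - 1) * (e - 1) - sum(
            gollob_df(g, e, n + 1) for n in range(k))
        rows.append(("Residual", resid_df, float(ss_axes[k:].sum())))
        if err_ms is not None:
            rows.append(("Error", err_df, ss_err))

        tested = {"Treatment", "Gene", "Tissue", "Interaction"} | {
            f"IPCA{n + 1}" for n in range(k)}
        recs = []
        for source, df, ss in rows:
            ms = ss / df if df > 0 else np.nan
            if source in tested and err_ms is not None:
                if err_ms <= 0:
                    raise ValueError("error mean square must be positive "
                                     "for F-tests")
                f, p = f_test(ms, df, err_ms, err_df)
            else:
                f, p = np.nan, np.nan
            pct = 100.0 * ss / ss_tot if source in (
                "Gene", "Tissue", "Interaction") else np.nan
            recs.append((source, df, ss, ms, f, p, pct))
        self.anova_table_ = pd.DataFrame(
            recs, columns=["source", "df", "ss", "ms", "f", "p", "pct_total"])

        self.interaction_ss_ = ss_int
        self.pct_of_total_ = {src: 100.0 * ss / ss_tot for src, ss in
                              [("Gene", ss_gene), ("Tissue", ss_tissue),
                               ("Interaction", ss_int)]}
        self.pct_of_interaction_ = {
            f"IPCA{n + 1}": 100.0 * float(ss_axes[n]) / ss_int
            for n in range(N)} if ss_int > 0 else {}
        return self

    # -- derived output -----------------------------------------------------
    def reconstruct(self, n_axes: int | None = None) -> np.ndarray:
        """Model means μ + α_g + β_e + Σ_{n≤n_axes} λ_n γ_gn δ_en."""
        if n_axes is None:
            n_axes = len(self.singular_values_)
        add = (self.grand_mean_ + self.gene_effects_[:, None]
               + self.tissue_effects_[None, :])
        mult = (self.gene_scores_[:, :n_axes]
                * self.singular_values_[:n_axes]) \
            @ self.tissue_scores_[:, :n_axes].T
        return add + mult

    def score_table(self) -> pd.DataFrame:
        """IPCA scores of genes and tissues in long form."""
        recs = []
        for i, name in enumerate(self.genes_):
            recs.append(["gene", name] + list(self.gene_scores_[i]))
        for j, name in enumerate(self.tissues_):
            recs.append(["tissue", name] + list(self.tissue_scores_[j]))
        cols = ["type", "name"] + [f"IPCA{n + 1}" for n in
                                   range(self.gene_scores_.shape[1])]
        return pd.DataFrame(recs, columns=cols)


def ammi_fit(m, n_components: int = 2) -> AMMI:
    """Fit :class:`AMMI` on a :class:`GEMatrix` (or array) and return it."""
    return AMMI(n_components=n_components).fit(m)
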
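"""Balanced-design analysis of variance from sufficient statistics.

Provides the sums-of-squares machinery shared by the AMMI decomposition and
the split-split-plot model:

* classical balanced factorial SS for any marginal term of the
  condition × tissue × gene crossing, computed from cell means and a common
  replicate count (:func:`factorial_ss`);
* the pooled within-cell error stratum recovered from per-cell standard
  deviations, ``SS = Σ (n−1)·sd²`` (:func:`error_ss_from_sd`);
* the three-stratum split-split-plot ANOVA
  (:class:`SplitSplitPlotAnova`) in which the main-plot factor
  (temperature) is tested against the block × temperature stratum, sub-plot
  terms (tissue and temperature × tissue) against the pooled
  block × tissue-within-temperature stratum, and sub-sub-plot terms (gene
  and its interactions) against the residual stratum.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_summary_table

FACTORS = ("condition", "tissue", "gene")

__all__ = [
    "factorial_ss",
    "error_ss_from_sd",
    "f_test",
    "SplitSplitPlotAnova",
    "split_split_plot_anova",
    "ssp_anova_cube",
    "SSP_SOURCES",
]


def f_test(ms_num: float, df_num: int, ms_den: float, df_den: int):
    """Variance-ratio test: F = ms_num / ms_den, p from the F upper tail."""
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ms_den <= 0:
        raise ValueError("denominator mean square must be positive")
    f = ms_num / ms_den
    p = float(stats.f.sf(f, df_num, df_den))
    return f, p


def _mean_cube(summary: pd.DataFrame):
    """Cell-mean cube with axes (condition, tissue, gene) and replicate r."""
    need = list(FACTORS) + ["mean", "n"]
    missing = [c for c in need if c not in summary.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    levels = [sorted(summary[f].unique()) for f in FACTORS]
    shape = tuple(len(l) for l in levels)
    if len(summary) != np.prod(shape):
        raise ValueError("design is incomplete: expected full "
                         f"{shape} crossing, got {len(summary)} cells")
    ns = summary["n"].unique()
    if len(ns) != 1:
        raise ValueError(f"unbalanced design: replicate counts {sorted(ns)}")
    if int(ns[0]) < 1:
        raise ValueError("replicate count must be >= 1")
    piv = summary.set_index(list(FACTORS))["mean"]
    cube = np.empty(shape)
    for idx, key in enumerate(np.ndindex(shape)):
        cube[key] = piv[tuple(levels[d][key[d]] for d in range(3))]
    return cube, levels, int(ns[0])


def factorial_ss(summary: pd.DataFrame, term) -> float:
    """Balanced-design sum of squares for a marginal term.

    ``term`` is a subset of ``{"condition", "tissue", "gene"}``; the empty
    subset is rejected.  The SS is on the observation scale: cell means are
    weighted by the common replicate count.  Main-effect and interaction SS
    over all seven non-empty terms add up to the treatment SS.
    """
    term = tuple(t for t in FACTORS if t in set(term))
    if not term:
        raise ValueError("term must name at least one factor")
    cube, levels, r = _mean_cube(summary)
    axes = {f: d for d, f in enumerate(FACTORS)}
    # inclusion-exclusion effect: sum over sub-margins with alternating sign
    eff = np.zeros_like(cube)
    for sub in chain.from_iterable(
            combinations(term, k) for k in range(len(term) + 1)):
        drop = tuple(axes[f] for f in FACTORS if f not in sub)
        margin = cube.mean(axis=drop, keepdims=True)
        eff = eff + (-1.0) ** (len(term) - len(sub)) * margin
    # eff broadcasts constant over non-term axes, so summing the full cube
    # already weights each term-margin effect by the other factors' sizes
    return float(r * (eff ** 2).sum())


def error_ss_from_sd(summary: pd.DataFrame):
    """Pooled within-cell error stratum from per-cell SDs.

    Returns ``(ss, df)`` with ``ss = Σ (n−1)·sd²`` and ``df = Σ (n−1)``.
    """
    validate_summary_table(summary)
    n = summary["n"].to_numpy(dtype=float)
    sd = summary["sd"].to_numpy(dtype=float)
    return float(((n - 1) * sd ** 2).sum()), int((n - 1).sum())


# ---------------------------------------------------------------------------
# split-split-plot ANOVA
# ---------------------------------------------------------------------------

SSP_SOURCES = [
    "Blocks", "Temperature", "Main-plot error",
    "Tissue", "Temperature x Tissue", "Sub-plot error",
    "Gene", "Temperature x Gene", "Tissue x Gene",
    "Temperature x Tissue x Gene", "Sub-sub-plot error",
]


def ssp_anova_cube(y: np.ndarray) -> pd.DataFrame:
    """Split-split-plot ANOVA of a complete balanced data cube.

    ``y`` has axes ``(block, temperature, tissue, gene)`` — one observation
    per cell, blocks being the replication.  Returns the ANOVA table with
    three error strata and F-tests of each fixed term against the error
    stratum of its own plot level.
    """
    if y.ndim != 4:
        raise ValueError("expected a (block, temperature, tissue, gene) cube")
    b, t, s, g = y.shape
    if min(b, t, s, g) < 2:
        raise ValueError("every factor needs at least 2 levels")
    N = y.size
    grand = y.mean()
    tot = ((y - grand) ** 2).sum()

    def between(axes_kept):
        """SS between cells of a margin, weighted by cell size."""
        drop = tuple(d for d in range(4) if d not in axes_kept)
        m = y.mean(axis=drop)
        return (N / m.size) * ((m - grand) ** 2).sum()

    ss_blocks = between((0,))
    ss_temp = between((1,))
    ss_main_err = between((0, 1)) - ss_blocks - ss_temp
    ss_tissue = between((2,))
    ss_ts = between((1, 2)) - ss_temp - ss_tissue
    ss_sub_err = (between((0, 1, 2)) - between((0, 1)) - ss_tissue - ss_ts)
    ss_gene = between((3,))
    ss_tg = between((1, 3)) - ss_temp - ss_gene
    ss_sg = between((2, 3)) - ss_tissue - ss_gene
    ss_tsg = (between((1, 2, 3)) - ss_temp - ss_tissue - ss_gene
              - ss_ts - ss_tg - ss_sg)
    ss_resid = (tot - ss_blocks - ss_temp - ss_main_err - ss_tissue - ss_ts
                - ss_sub_err - ss_gene - ss_tg - ss_sg - ss_tsg)

    dfs = [b - 1, t - 1, (b - 1) * (t - 1),
           s - 1, (t - 1) * (s - 1), t * (b - 1) * (s - 1),
           g - 1, (t - 1) * (g - 1), (s - 1) * (g - 1),
           (t - 1) * (s - 1) * (g - 1), t * s * (b - 1) * (g - 1)]
    sss = [ss_blocks, ss_temp, ss_main_err, ss_tissue, ss_ts, ss_sub_err,
           ss_gene, ss_tg, ss_sg, ss_tsg, ss_resid]
    mss = [ss / df for ss, df in zip(sss, dfs)]

    err_of = {1: 2, 3: 5, 4: 5, 6: 10, 7: 10, 8: 10, 9: 10}
    fvals, pvals = [], []
    for i in range(len(SSP_SOURCES)):
        j = err_of.get(i)
        if j is None or mss[j] <= 0:
            fvals.append(np.nan)
            pvals.append(np.nan)
        else:
            f, p = f_test(mss[i], dfs[i], mss[j], dfs[j])
            fvals.append(f)
            pvals.append(p)
    return pd.DataFrame({"source": SSP_SOURCES, "df": dfs, "ss": sss,
                         "ms": mss, "f": fvals, "p": pvals})


class SplitSplitPlotAnova:
    """Split-split-plot ANOVA for a blocked temperature/tissue/gene design.

    The design has blocks as complete replicates, a main-plot factor
    (temperature), a sub-plot factor (tissue) nested in main plots and a
    sub-sub-plot factor (gene) nested in sub-plots, each randomisation tier
    carrying its own error stratum.

    Parameters
    ----------
    condition_col, tissue_col, gene_col, block_col, value_col : str
        Column names in the long-format table passed to :meth:`fit`.

    Attributes
    ----------
    anova_table_ : pandas.DataFrame
        Rows ``Blocks, Temperature, Main-plot error, Tissue,
        Temperature x Tissue, Sub-plot error, Gene, Temperature x Gene,
        Tissue x Gene, Temperature x Tissue x Gene, Sub-sub-plot error``
        with columns source/df/ss/ms/f/p.
    design_ : dict
        Numbers of blocks and factor levels, ``{"b", "t", "s", "g"}``.
    """

    def __init__(self, condition_col="condition", tissue_col="tissue",
                 gene_col="gene", block_col="block", value_col="expression"):
        self.condition_col = condition_col
        self.tissue_col = tissue_col
        self.gene_col = gene_col
        self.block_col = block_col
        self.value_col = value_col

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("condition_col", "tissue_col", "gene_col", "block_col",
                 "value_col")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame):
        cols = [self.block_col, self.condition_col, self.tissue_col,
                self.gene_col]
        missing = [c for c in cols + [self.value_col]
                   if c not in table.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        levels = [np.sort(table[c].unique()) for c in cols]
        shape = tuple(len(l) for l in levels)
        piv = table.set_index(cols)[self.value_col]
        if len(piv) != int(np.prod(shape)) or piv.index.duplicated().any():
            full = pd.MultiIndex.from_product(levels, names=cols)
            absent = full.difference(piv.index)
            raise ValueError(
                f"incomplete design: {len(absent)} missing cells, e.g. "
                f"{list(absent[:5])}")
        cube = piv.reindex(
            pd.MultiIndex.from_product(levels, names=cols)
        ).to_numpy().reshape(shape)
        self.anova_table_ = ssp_anova_cube(cube)
        self.design_ = dict(zip("btsg", shape))
        return self


def split_split_plot_anova(table: pd.DataFrame, **columns) -> pd.DataFrame:
    """Functional wrapper: fit :class:`SplitSplitPlotAnova`, return the table."""
    return SplitSplitPlotAnova(**columns).fit(table).anova_table_
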
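"""Expression-table input/output and relative quantification.

Two tabular layouts are used throughout the package, both plain
:class:`pandas.DataFrame` objects:

* an **expression table** holds replicate-level relative-expression records
  with columns ``condition, tissue, gene, block, expression`` — one row per
  qPCR fold-change measurement;
* a **summary table** holds sufficient statistics per
  condition × tissue × gene cell with columns
  ``condition, tissue, gene, mean, sd, n``.

All analysis of variance in this package runs off sufficient statistics, so
a summary table (for example one transcribed from a published
means ± SD table) is a complete input.  :func:`expand` turns a summary table
back into pseudo-replicates whose sample moments match the summary exactly,
which lets replicate-level routines (the split-split-plot ANOVA, simulation
checks) run on summary-only data.

The packaged fixture (:func:`load_fixture_table2`) is the 4-gene × 9-tissue ×
4-temperature table of relative expression of the cold-resistance genes
AFP1, CIRP, HMGB1 and YB-1 measured in *Takifugu rubripes* at 18, 13, 8 and
5 °C (n = 3 per cell).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

EXPRESSION_COLUMNS = ["condition", "tissue", "gene", "block", "expression"]
SUMMARY_COLUMNS = ["condition", "tissue", "gene", "mean", "sd", "n"]

__all__ = [
    "relative_expression",
    "summarize",
    "expand",
    "load_fixture_table2",
    "read_expression_csv",
    "write_expression_csv",
    "read_summary_csv",
    "write_summary_csv",
    "validate_expression_table",
    "validate_summary_table",
]


def relative_expression(ct_target, ct_ref, ct_target_cal, ct_ref_cal):
    """Relative expression fold-change by the 2^−ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference) is computed for the sample and for the
    calibrator; the fold-change is ``2**-(ΔCt_sample − ΔCt_calibrator)``.
    Accepts scalars or broadcastable arrays of cycle-threshold values.

    Parameters
    ----------
    ct_target, ct_ref : float or array-like
        Ct of the target and reference gene in the sample of interest.
    ct_target_cal, ct_ref_cal : float or array-like
        Ct of the target and reference gene in the calibrator sample.

    Returns
    -------
    float or ndarray
        Strictly positive fold-change relative to the calibrator.
    """
    cts = [np.asarray(c, dtype=float) for c in
           (ct_target, ct_ref, ct_target_cal, ct_ref_cal)]
    for c in cts:
        if not np.all(np.isfinite(c)):
            raise ValueError("all Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    out = np.exp2(-ddct)
    return float(out) if out.ndim == 0 else out


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column layout and key uniqueness.

    Fold-change data are non-negative by construction, but simulated
    observations on the raw scale (Gaussian error strata) may dip below
    zero, so non-negativity is deliberately not enforced here.
    """
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    keys = table[["condition", "tissue", "gene", "block"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (condition, tissue, gene, block): {dup}")
    return table


def validate_summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMMARY_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    if (summary["sd"] < 0).any() or (summary["mean"] < 0).any():
        raise ValueError("summary mean and sd must be non-negative")
    if (summary["n"] < 2).any():
        bad = summary.loc[summary["n"] < 2].iloc[0]
        raise ValueError(
            "cell ({}, {}, {}) has n = {} (< 2)".format(
                bad["condition"], bad["tissue"], bad["gene"], bad["n"]))
    return summary


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a replicate-level expression table to per-cell (mean, sd, n).

    The standard deviation is the sample SD (n − 1 denominator); cells with a
    single replicate are rejected because their SD is undefined.
    """
    validate_expression_table(table)
    grouped = table.groupby(["condition", "tissue", "gene"], sort=True)
    agg = grouped["expression"].agg(mean="mean", sd=lambda v: v.std(ddof=1),
                                    n="count").reset_index()
    single = agg[agg["n"] < 2]
    if len(single):
        cell = single.iloc[0]
        raise ValueError(
            "cell ({}, {}, {}) has a single replicate; need n >= 2".format(
                cell["condition"], cell["tissue"], cell["gene"]))
    agg["n"] = agg["n"].astype(int)
    return agg[SUMMARY_COLUMNS]


def expand(summary: pd.DataFrame, seed: int | np.random.Generator = 0,
           ) -> pd.DataFrame:
    """Generate pseudo-replicates matching each cell's mean and SD exactly.

    For each cell, n standard-normal draws are affinely rescaled so the
    sample mean and sample SD (n − 1 denominator) equal the cell's values to
    machine precision.  Draws are retried a few times if the rescaled values
    would dip below zero (possible for high-CV cells); exact moments always
    take precedence over non-negativity.  Deterministic given ``seed``.
    """
    validate_summary_table(summary)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = []
    for rec in summary.itertuples(index=False):
        n = int(rec.n)
        if rec.sd == 0:
            vals = np.full(n, float(rec.mean))
        else:
            for _ in range(64):
                z = rng.standard_normal(n)
                z = z - z.mean()
                s = z.std(ddof=1)
                if s == 0:  # pathological draw, retry
                    continue
                vals = rec.mean + rec.sd * z / s
                if (vals >= 0).all():
                    break
        for k, v in enumerate(vals, start=1):
            rows.append((rec.condition, rec.tissue, rec.gene, k, v))
    out = pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)
    # clip the rare still-negative value is NOT done: moments are the contract
    return out


def load_fixture_table2() -> pd.DataFrame:
    """Packaged cold-resistance gene expression summary for *T. rubripes*.

    144 cells: 4 genes (AFP1, CIRP, HMGB1, YB-1) × 9 tissues × 4 water
    temperatures (18, 13, 8, 5 °C), mean ± sample SD of n = 3 replicate
    fold-changes (2^−ΔΔCt against β-actin).
    """
    with resources.files("geitools.data").joinpath(
            "table2_summary.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return validate_summary_table(df)


def read_expression_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_expression_table(df)


def write_expression_csv(table: pd.DataFrame, path) -> None:
    validate_expression_table(table)
    table.to_csv(path, index=False)


def read_summary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_summary_table(df)


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    validate_summary_table(summary)
    summary.to_csv(path, index=False)
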
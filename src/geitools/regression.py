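"""Expression-versus-temperature curve families and family selection.

Each gene × tissue series of mean expression against water temperature is
fitted with three candidate families:

* ``power`` — y = a·x^b, fitted as a straight line in log–log space; its r²
  is reported in log space,
* ``poly2`` — quadratic polynomial,
* ``poly3`` — cubic polynomial (with four temperatures it interpolates).

Because a cubic through four points always fits perfectly, family selection
uses a parsimony rule: the smallest family whose r² reaches ``1 − tau``
wins, with the power family preferred first.  The rule makes the selected
labels reproducible and comparable; it is stated explicitly because visual
curve choice is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegressionFit", "fit_family", "select_family", "scan_families",
           "TemperatureResponseRegression", "FAMILIES"]

FAMILIES = ("power", "poly2", "poly3")
_N_PARAMS = {"power": 2, "poly2": 3, "poly3": 4}


@dataclass
class RegressionFit:
    family: str
    coefficients: np.ndarray   # power: (a, b); polyN: numpy poly coeffs
    r2: float
    n_points: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "power":
            a, b = self.coefficients
            return a * np.power(x, b)
        return np.polyval(self.coefficients, x)


def _r2(y, yhat):
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 1.0


def fit_family(x, y, family: str) -> RegressionFit:
    """Least-squares fit of one candidate family.

    The power family is fitted as a log–log linear regression and its r² is
    the log-space coefficient of determination; polynomials are ordinary
    least squares on the raw scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < _N_PARAMS[family]:
        raise ValueError(f"{family} needs >= {_N_PARAMS[family]} points")
    if family == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power family needs strictly positive x and y")
        lx, ly = np.log(x), np.log(y)
        b, loga = np.polyfit(lx, ly, 1)
        return RegressionFit("power", np.array([np.exp(loga), b]),
                             _r2(ly, loga + b * lx), len(x))
    deg = 2 if family == "poly2" else 3
    coeffs = np.polyfit(x, y, deg)
    return RegressionFit(family, coeffs, _r2(y, np.polyval(coeffs, x)),
                         len(x))


def select_family(x, y, tau: float = 0.01) -> str:
    """Pick the most parsimonious family with r² ≥ 1 − tau.

    Candidates are tried in the order power, quadratic, cubic; the power
    family is skipped when the data are not strictly positive.  If no
    family reaches the threshold the cubic (largest) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < _N_PARAMS[FAMILIES[0]]:
        raise ValueError("need at least 2 points")
    for family in FAMILIES:
        if len(x) < _N_PARAMS[family]:
            continue
        if family == "power" and (np.any(x <= 0) or np.any(y <= 0)):
            continue
        if fit_family(x, y, family).r2 >= 1.0 - tau:
            return family
    return "poly3" if len(x) >= 4 else "poly2"


def scan_families(summary: pd.DataFrame, tau: float = 0.01) -> pd.DataFrame:
    """Fit all families to every gene × tissue temperature series.

    Returns one row per gene × tissue with the selected family, each
    family's r² and the selected family's coefficients.
    """
    recs = []
    for (gene, tissue), grp in summary.groupby(["gene", "tissue"]):
        grp = grp.sort_values("condition")
        x = grp["condition"].to_numpy(dtype=float)
        y = grp["mean"].to_numpy(dtype=float)
        r2s = {}
        for family in FAMILIES:
            try:
                r2s[family] = fit_family(x, y, family).r2
            except ValueError:
                r2s[family] = np.nan
        sel = select_family(x, y, tau=tau)
        coefs = fit_family(x, y, sel).coefficients
        recs.append({"gene": gene, "tissue": tissue, "family": sel,
                     "r2_power": r2s["power"], "r2_poly2": r2s["poly2"],
                     "r2_poly3": r2s["poly3"],
                     "coefficients": " ".join(f"{c:.6g}" for c in coefs)})
    return pd.DataFrame(recs)


class TemperatureResponseRegression:
    """Estimator wrapper around the family fits.

    Parameters
    ----------
    family : str or "auto"
        Fixed family, or "auto" to apply the parsimony selection rule.
    tau : float
        r² tolerance of the selection rule (only used with "auto").

    Attributes
    ----------
    fit_ : RegressionFit
    family_ : str
    """

    def __init__(self, family: str = "auto", tau: float = 0.01):
        self.family = family
        self.tau = tau

    def get_params(self, deep=True):
        return {"family": self.family, "tau": self.tau}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, x, y):
        fam = self.family
        if fam == "auto":
            fam = select_family(x, y, tau=self.tau)
        self.fit_ = fit_family(x, y, fam)
        self.family_ = fam
        return self

    def predict(self, x):
        return self.fit_.predict(x)
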
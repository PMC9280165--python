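"""Seeded forward simulators for the two models the package fits.

Two generators produce replicate-level expression tables with known ground
truth:

* :func:`simulate_ammi` draws from the AMMI forward model — additive
  genotype and tissue effects plus a low-rank multiplicative interaction
  (orthonormal, column-centered score matrices) and i.i.d. Gaussian
  replicate noise on the raw expression scale;
* :func:`simulate_ssp` draws from the split-split-plot model — fixed block
  and treatment effects plus three independent Gaussian error strata
  (main-plot, sub-plot and residual sub-sub-plot).

Both are deterministic given their spec's seed, which makes exact
parameter-recovery and type-I-error tests possible without stored data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EXPRESSION_COLUMNS

__all__ = ["AmmiSimSpec", "SspSimSpec", "simulate_ammi", "simulate_ssp",
           "random_interaction_scores", "ammi_spec_from_dict",
           "ssp_spec_from_dict"]


def random_interaction_scores(g: int, e: int, rank: int, seed=0):
    """Orthonormal, column-centered score matrices (γ, δ) for simulation.

    Gaussian draws are centered per column (so interaction effects sum to
    zero over genotypes and environments) and orthonormalised by QR.  The
    centering is preserved by QR because the centered columns span a
    subspace orthogonal to the all-ones vector.
    """
    if not 1 <= rank <= min(g - 1, e - 1):
        raise ValueError(f"rank must be in [1, {min(g - 1, e - 1)}]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    def make(m):
        a = rng.standard_normal((m, rank))
        a -= a.mean(axis=0, keepdims=True)
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # deterministic orientation
        return q

    return make(g), make(e)


@dataclass
class AmmiSimSpec:
    """Ground truth for the AMMI forward model.

    ``alpha`` (length g) and ``beta`` (length e) must sum to zero;
    ``gamma`` (g × N) and ``delta`` (e × N) must have orthonormal,
    zero-sum columns; ``singular_values`` (length N) must be descending and
    non-negative.  ``noise_sd`` is the replicate-level Gaussian SD and
    ``r`` the number of replicates per cell.
    """

    g: int
    e: int
    r: int
    mu: float = 0.0
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))
    gamma: np.ndarray | None = None
    delta: np.ndarray | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.g, self.e) < 2 or self.r < 1:
            raise ValueError("need g, e >= 2 and r >= 1")
        self.alpha = np.zeros(self.g) if self.alpha is None \
            else np.asarray(self.alpha, dtype=float)
        self.beta = np.zeros(self.e) if self.beta is None \
            else np.asarray(self.beta, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if len(self.alpha) != self.g or abs(self.alpha.sum()) > 1e-8 * max(
                1.0, np.abs(self.alpha).max()):
            raise ValueError("alpha must have length g and sum to 0")
        if len(self.beta) != self.e or abs(self.beta.sum()) > 1e-8 * max(
                1.0, np.abs(self.beta).max()):
            raise ValueError("beta must have length e and sum to 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        N = len(self.singular_values)
        if N:
            if np.any(np.diff(self.singular_values) > 1e-12) or np.any(
                    self.singular_values < 0):
                raise ValueError("singular_values must be descending and "
                                 ">= 0")
            if N > min(self.g - 1, self.e - 1):
                raise ValueError("too many interaction axes for the table "
                                 "size")
            for name, m, rows in (("gamma", self.gamma, self.g),
                                  ("delta", self.delta, self.e)):
                if m is None:
                    raise ValueError(f"{name} required when "
                                     "singular_values given")
                m = np.asarray(m, dtype=float)
                if m.shape != (rows, N):
                    raise ValueError(f"{name} must be {rows} x {N}")
                if not np.allclose(m.T @ m, np.eye(N), atol=1e-8):
                    raise ValueError(f"{name} columns must be orthonormal")
                if not np.allclose(m.sum(axis=0), 0, atol=1e-8):
                    raise ValueError(f"{name} columns must sum to 0")
            self.gamma = np.asarray(self.gamma, dtype=float)
            self.delta = np.asarray(self.delta, dtype=float)

    @property
    def cell_means(self) -> np.ndarray:
        """Expected g × e table: μ + α_g + β_e + Σ λ_n γ_gn δ_en."""
        mean = self.mu + self.alpha[:, None] + self.beta[None, :]
        if len(self.singular_values):
            mean = mean + (self.gamma * self.singular_values) @ self.delta.T
        return mean


def simulate_ammi(spec: AmmiSimSpec) -> pd.DataFrame:
    """Replicate-level expression table drawn from the AMMI model."""
    rng = np.random.default_rng(spec.seed)
    mean = spec.cell_means
    y = mean[:, :, None] + spec.noise_sd * rng.standard_normal(
        (spec.g, spec.e, spec.r))
    rows = []
    for i in range(spec.g):
        for j in range(spec.e):
            for k in range(spec.r):
                rows.append((0, f"E{j + 1}", f"G{i + 1}", k + 1, y[i, j, k]))
    return pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)


@dataclass
class SspSimSpec:
    """Ground truth for the split-split-plot forward model.

    Fixed effects default to zero; any provided effect array must match the
    full factorial shape of its factors.  ``sigma_main``, ``sigma_sub`` and
    ``sigma`` are the SDs of the main-plot, sub-plot and residual error
    strata.
    """

    b: int
    t: int
    s: int
    g: int
    mu: float = 0.0
    temp_effects: np.ndarray | None = None        # length t
    tissue_effects: np.ndarray | None = None      # length s
    gene_effects: np.ndarray | None = None        # length g
    treatment_effects: np.ndarray | None = None   # t x s x g, overrides above
    block_effects: np.ndarray | None = None       # length b
    sigma_main: float = 1.0
    sigma_sub: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.b, self.t, self.s, self.g) < 2:
            raise ValueError("all of b, t, s, g must be >= 2")
        for sd in (self.sigma_main, self.sigma_sub, self.sigma):
            if sd < 0:
                raise ValueError("error-strata SDs must be >= 0")

    @property
    def cell_effects(self) -> np.ndarray:
        """The t × s × g fixed treatment surface d_ihj."""
        if self.treatment_effects is not None:
            d = np.asarray(self.treatment_effects, dtype=float)
            if d.shape != (self.t, self.s, self.g):
                raise ValueError("treatment_effects must be t x s x g")
            return d
        d = np.zeros((self.t, self.s, self.g))
        if self.temp_effects is not None:
            d = d + np.asarray(self.temp_effects,
                               dtype=float)[:, None, None]
        if self.tissue_effects is not None:
            d = d + np.asarray(self.tissue_effects,
                               dtype=float)[None, :, None]
        if self.gene_effects is not None:
            d = d + np.asarray(self.gene_effects, dtype=float)[None, None, :]
        return d


def _ssp_cube(spec: SspSimSpec, rng: np.random.Generator) -> np.ndarray:
    """One (b, t, s, g) draw from the split-split-plot model."""
    b, t, s, g = spec.b, spec.t, spec.s, spec.g
    blocks = np.zeros(b) if spec.block_effects is None \
        else np.asarray(spec.block_effects, dtype=float)
    f_ik = spec.sigma_main * rng.standard_normal((b, t))
    g_ihk = spec.sigma_sub * rng.standard_normal((b, t, s))
    e_ihjk = spec.sigma * rng.standard_normal((b, t, s, g))
    return (spec.mu + blocks[:, None, None, None]
            + spec.cell_effects[None, :, :, :]
            + f_ik[:, :, None, None] + g_ihk[:, :, :, None] + e_ihjk)


def simulate_ssp(spec: SspSimSpec, n_datasets: int | None = None):
    """Replicate-level table (or a stack of cubes) from the split-split-plot
    model.

    With ``n_datasets=None`` a long-format expression table is returned
    (blocks numbered 1..b).  With an integer ``n_datasets`` a
    ``(n_datasets, b, t, s, g)`` array of independent draws is returned —
    the compact form used for Monte-Carlo calibration.
    """
    rng = np.random.default_rng(spec.seed)
    if n_datasets is not None:
        return np.stack([_ssp_cube(spec, rng) for _ in range(n_datasets)])
    y = _ssp_cube(spec, rng)
    b, t, s, g = y.shape
    idx = pd.MultiIndex.from_product(
        [range(1, b + 1), [f"T{i + 1}" for i in range(t)],
         [f"S{h + 1}" for h in range(s)], [f"G{j + 1}" for j in range(g)]],
        names=["block", "condition", "tissue", "gene"])
    out = pd.DataFrame({"expression": y.ravel()}, index=idx).reset_index()
    return out[EXPRESSION_COLUMNS]


# -- config-file plumbing ---------------------------------------------------

def ammi_spec_from_dict(cfg: dict) -> AmmiSimSpec:
    """Build an :class:`AmmiSimSpec` from a YAML/JSON-style mapping.

    Score matrices may be given explicitly or requested implicitly via
    ``interaction_rank`` (drawn from the spec's seed).
    """
    cfg = dict(cfg)
    rank = cfg.pop("interaction_rank", None)
    if rank and "gamma" not in cfg:
        gamma, delta = random_interaction_scores(
            cfg["g"], cfg["e"], rank, seed=cfg.get("seed", 0))
        cfg["gamma"], cfg["delta"] = gamma, delta
    return AmmiSimSpec(**cfg)


def ssp_spec_from_dict(cfg: dict) -> SspSimSpec:
    return SspSimSpec(**cfg)
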
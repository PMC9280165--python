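"""Optional rendering of GGE biplot views.

Coordinates are the contract of this package; these helpers only draw them.
Imported lazily so headless use never touches matplotlib.
"""

from __future__ import annotations

import numpy as np


def plot_gge_panels(model, path=None, title=None):
    """Draw the four standard views (relationships, which-won-where,
    mean vs stability, ideal-gene circles) into a 2 × 2 figure.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = model.gene_coords_[:, :2]
    E = model.tissue_coords_[:, :2]
    fig, axes = plt.subplots(2, 2, figsize=(10, 10))
    for ax in axes.ravel():
        ax.axhline(0, color="0.8", lw=0.8)
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_aspect("equal", adjustable="datalim")
        for i, name in enumerate(model.genes_):
            ax.annotate(str(name), G[i], color="tab:blue", fontsize=9,
                        fontweight="bold")
        for j, name in enumerate(model.tissues_):
            ax.annotate(str(name), E[j], color="tab:green", fontsize=8)
        ax.scatter(G[:, 0], G[:, 1], c="tab:blue", s=12)
        ax.scatter(E[:, 0], E[:, 1], c="tab:green", s=10, marker="^")

    # A: tissue vectors
    ax = axes[0, 0]
    for j in range(len(model.tissues_)):
        ax.plot([0, E[j, 0]], [0, E[j, 1]], color="tab:green", lw=0.8)
    ax.set_title("tissue relationships")

    # B: hull polygon and sector rays
    ax = axes[0, 1]
    part = model.which_won_where()
    hull_idx = [model.genes_.index(g) for g in part.hull]
    poly = G[hull_idx + hull_idx[:1]]
    ax.plot(poly[:, 0], poly[:, 1], color="tab:blue", lw=1)
    rmax = 1.1 * max(np.abs(G).max(), np.abs(E).max())
    for ang in part.rays:
        ax.plot([0, rmax * np.cos(ang)], [0, rmax * np.sin(ang)],
                color="0.5", ls="--", lw=0.8)
    ax.set_title("which-won-where")

    # C: average-tissue axis and perpendicular
    ax = axes[1, 0]
    ata = model._ata()
    span = 1.2 * max(np.abs(G).max(), np.abs(E).max())
    ax.plot([-span * ata[0], span * ata[0]],
            [-span * ata[1], span * ata[1]], color="k", lw=1)
    ax.plot([-span * ata[1], span * ata[1]],
            [span * ata[0], -span * ata[0]], color="k", lw=0.8, ls=":")
    ax.set_title("mean vs stability")

    # D: concentric circles around the ideal gene
    ax = axes[1, 1]
    rank = model.ideal_gene_distance()
    radius = np.linalg.norm(G, axis=1).max()
    center = ata * radius
    for r in np.linspace(0.25, 1.0, 4) * radius:
        ax.add_patch(plt.Circle(center, r, fill=False, color="0.6",
                                lw=0.7))
    ax.scatter(*center, marker="*", s=80, color="tab:red")
    ax.set_title("ideal gene")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
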
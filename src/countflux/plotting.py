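"""Trace and posterior-density figures for fitted chains.

One panel pair per top-level parameter: the marginal posterior density
with 68% and 95% highest-density regions shaded, next to the MCMC trace.
Shading bounds come straight from :func:`countflux.mcmc.summarize_posterior`
so figures and tables cannot disagree.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gaussian_kde

from .exceptions import ValidationError
from .mcmc import PosteriorChains, summarize_posterior

__all__ = ["render_outputs", "plot_parameter_panel"]


def plot_parameter_panel(ax_density, ax_trace, draws, name: str) -> None:
    """Draw one density panel (with HDR shading) and one trace panel."""
    draws = np.asarray(draws, dtype=float)
    s = summarize_posterior(draws)
    if np.ptp(draws) > 0:
        kde = gaussian_kde(draws)
        lo, hi = draws.min(), draws.max()
        pad = 0.1 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, 400)
        dens = kde(grid)
        ax_density.plot(grid, dens, color="black", lw=1)
        for level, color in ((0.95, "0.85"), (0.68, "0.55")):
            a, b = s["hdr"][level]
            mask = (grid >= a) & (grid <= b)
            ax_density.fill_between(grid[mask], dens[mask], color=color)
    else:
        ax_density.axvline(draws[0], color="black")
    ax_density.set_title(name)
    ax_density.set_ylabel("density")
    ax_trace.plot(draws, lw=0.3, color="black")
    ax_trace.set_ylabel(name)
    ax_trace.set_xlabel("retained iteration")


def render_outputs(chains: PosteriorChains, bf_table=None, out_dir=".") -> dict:
    """Write trace/density figures (and optionally the BF table CSV).

    Returns a dict of artifact paths.  Regenerates everything from the
    persisted draws alone; no MCMC is re-run.
    """
    if chains.n_retained == 0:
        raise ValidationError("empty chains; nothing to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(chains.parameter_names)
    fig, axes = plt.subplots(
        len(names), 2, figsize=(9, 2.2 * len(names)), squeeze=False
    )
    for i, name in enumerate(names):
        plot_parameter_panel(axes[i][0], axes[i][1], chains[name], name)
    fig.tight_layout()
    fig_path = out_dir / f"posterior_{chains.model.name}.png"
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    artifacts = {"figure": fig_path}
    if bf_table is not None:
        table_path = out_dir / "bayes_factors.csv"
        bf_table.to_csv(table_path)
        artifacts["bf_table"] = table_path
    return artifacts
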
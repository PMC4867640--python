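"""Diagnostic plots for dispersion and terrain results."""

from __future__ import annotations

import numpy as np

from .pattern import DispersionResult

__all__ = ["plot_l_function", "plot_quadrat_counts"]


def plot_l_function(result: DispersionResult, ax=None):
    """L(t) with its shaded Monte-Carlo envelope; L = 0 marks randomness."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(
        result.t_grid,
        result.l_env_low,
        result.l_env_high,
        color="0.8",
        label=f"95% envelope (n={result.n_sim})",
    )
    ax.plot(result.t_grid, result.l_obs, "k-", label="observed")
    ax.axhline(0.0, color="0.4", lw=0.5)
    ax.set_xlabel("t (m along track)")
    ax.set_ylabel("L(t)")
    ax.set_title(f"{result.taxon} (N={result.n})")
    ax.legend(frameon=False)
    return ax


def plot_quadrat_counts(cell_counts: np.ndarray, n: int = 11, ax=None):
    """Heatmap of the 11 x 11 quadrat cell counts."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(np.asarray(cell_counts).reshape(n, n), origin="lower", cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="fish per cell")
    ax.set_xlabel("cell column")
    ax.set_ylabel("cell row")
    return ax
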
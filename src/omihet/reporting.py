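"""Figure rendering: effect-size heatmaps and subpopulation density plots.

Every figure gets a CSV twin containing exactly the plotted numbers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .heterogeneity import SubpopulationModel, density_curves


def render_heatmap(
    report: pd.DataFrame,
    png_path: str | Path,
    csv_path: str | Path,
    threshold: float = 0.75,
) -> list[Path]:
    """Patients x treatments heatmap of the OMI index Glass's Delta.

    Cells at or above the effect-size threshold are marked with an asterisk.
    """
    if report.empty:
        raise ValueError("empty response report")
    matrix = report.pivot_table(index="patient_id", columns="treatment",
                                values="glass_delta")
    matrix.to_csv(csv_path)
    fig, ax = plt.subplots(figsize=(1.2 + matrix.shape[1], 1.0 + 0.6 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu", aspect="auto",
                   vmin=-max(1.0, np.nanmax(np.abs(matrix.to_numpy()))),
                   vmax=max(1.0, np.nanmax(np.abs(matrix.to_numpy()))))
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            val = matrix.iat[i, j]
            if np.isfinite(val):
                star = "*" if val >= threshold else ""
                ax.text(j, i, f"{val:.2f}{star}", ha="center", va="center", fontsize=8)
    ax.set_title("OMI index treatment effect size (Glass's $\\Delta$)")
    fig.colorbar(im, ax=ax, label="Glass's $\\Delta$")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return [Path(png_path), Path(csv_path)]


def render_density(
    control: SubpopulationModel,
    treated: SubpopulationModel,
    png_path: str | Path,
    csv_path: str | Path,
    n_grid: int = 512,
) -> list[Path]:
    """Overlaid area-normalized mixture densities for control vs. treated.

    The annotation gives the selected number of subpopulations per group.
    """
    lo = min(control.mu.min() - 5 * control.sigma.max(),
             treated.mu.min() - 5 * treated.sigma.max())
    hi = max(control.mu.max() + 5 * control.sigma.max(),
             treated.mu.max() + 5 * treated.sigma.max())
    grid = np.linspace(lo, hi, n_grid)
    c_total, c_comps = density_curves(control, grid)
    t_total, t_comps = density_curves(treated, grid)
    twin = pd.DataFrame({"x": grid, "control_total": c_total, "treated_total": t_total})
    for i in range(control.g):
        twin[f"control_comp{i + 1}"] = c_comps[i]
    for i in range(treated.g):
        twin[f"treated_comp{i + 1}"] = t_comps[i]
    twin.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(grid, c_total, color="0.3", label=f"control [{control.g}]")
    ax.plot(grid, t_total, color="crimson", label=f"treated [{treated.g}]")
    for i in range(control.g):
        ax.plot(grid, c_comps[i], color="0.3", ls="--", lw=0.8)
    for i in range(treated.g):
        ax.plot(grid, t_comps[i], color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("OMI index")
    ax.set_ylabel("normalized density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return [Path(png_path), Path(csv_path)]
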
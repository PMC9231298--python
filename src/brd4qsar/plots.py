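"""Diagnostic plots: Williams plot, Y-scrambling scatter, Q2 size curve."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import BreakingPoint
from .validation import DomainDiagnostics, YScrambleResult


def williams_plot(diag: DomainDiagnostics, path: Optional[str] = None, ax=None):
    """Leverage vs standardized residual with h* and +/-3 boundaries."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    tr = diag.is_training
    ax.scatter(diag.leverages[tr], diag.std_residuals[tr], s=14,
               label="training", alpha=0.7)
    if (~tr).any():
        ax.scatter(diag.leverages[~tr], diag.std_residuals[~tr], s=14,
                   marker="^", label="external", alpha=0.7)
    ax.axvline(diag.h_star, color="k", lw=1,
               label=f"h* = {diag.h_star:.3f}")
    for bound in (-3, 3):
        ax.axhline(bound, color="k", ls="--", lw=0.8)
    ax.set_xlabel("leverage $h_i$")
    ax.set_ylabel("standardized residual")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def yscramble_plot(result: YScrambleResult, r2_real: float, q2_real: float,
                   path: Optional[str] = None, ax=None):
    """Scrambled-run R2/Q2 cloud against the real model's statistics."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(result.r2_values, result.q2_values, s=10, alpha=0.5,
               label="scrambled")
    ax.scatter([r2_real], [q2_real], s=60, marker="*", color="crimson",
               label="model")
    ax.set_xlabel("$R^2$")
    ax.set_ylabel("$Q^2_{LOO}$")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def q2_size_curve(result: BreakingPoint, path: Optional[str] = None, ax=None):
    """Best Q2_LOO per model size, with the chosen breaking point marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.sizes, result.q2_curve, "o-")
    ax.axvline(result.chosen_size, color="k", ls=":",
               label=f"breaking point = {result.chosen_size}")
    ax.set_xlabel("number of descriptors")
    ax.set_ylabel("$Q^2_{LOO}$")
    ax.legend(fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
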
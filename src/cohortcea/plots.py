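"""Matplotlib figures: CE plane scatter, acceptability curve, tornado."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import CEACCurve, PSASample, TornadoEntry

__all__ = ["plot_ce_plane", "plot_ceac", "plot_tornado"]


def plot_ce_plane(
    samples: Sequence[PSASample],
    wtp: float | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Scatter of incremental QALYs vs incremental cost, one point per
    Monte-Carlo repetition, with an optional WTP threshold line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    de = np.array([s.delta_qaly for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    ax.scatter(de, dc, s=8, alpha=0.4, edgecolors="none")
    ax.axhline(0.0, color="0.4", lw=0.8)
    ax.axvline(0.0, color="0.4", lw=0.8)
    if wtp is not None:
        xs = np.linspace(de.min(), de.max(), 50)
        ax.plot(xs, wtp * xs, "--", color="tab:red", lw=1,
                label=f"WTP ${wtp:,.0f}/QALY")
        ax.legend(frameon=False)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.set_title("Cost-effectiveness plane")
    return ax


def plot_ceac(curve: CEACCurve, ax: plt.Axes | None = None) -> plt.Axes:
    """Probability of cost-effectiveness against willingness to pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, marker=".", lw=1.2)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay ($ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax


def plot_tornado(
    entries: Iterable[TornadoEntry],
    base_icer: float,
    top: int = 10,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Horizontal tornado bars around the base-case ICER, widest on top."""
    entries = sorted(entries, key=lambda e: e.width, reverse=True)[:top]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(entries) + 1.5))
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="tab:blue", alpha=0.7)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER ($ per QALY)")
    ax.set_title("One-way sensitivity (tornado)")
    return ax
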
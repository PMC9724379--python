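"""Optional figures: cost-effectiveness plane, tornado bars, CEAC curve."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sensitivity import CEACPoint, PSAResult, TornadoEntry


def ce_plane(psa: PSAResult, path: Path) -> None:
    """Scatter of (dQALY, dCost) replications with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qaly, psa.delta_cost, s=4, alpha=0.3, linewidths=0)
    lim = float(np.abs(psa.delta_qaly).max()) * 1.05
    xs = np.array([-lim, lim])
    ax.plot(xs, psa.model.wtp * xs, "r--", lw=1, label=f"WTP = {psa.model.wtp:g}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tornado_plot(entries: Sequence[TornadoEntry], path: Path) -> None:
    """Horizontal bars of INMB at low/high input, widest spread on top."""
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(entries) + 1.5))
    names = [e.parameter for e in entries][::-1]
    for i, e in enumerate(reversed(entries)):
        lo, hi = sorted((e.outcome_at_low, e.outcome_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
        ax.plot([e.base_outcome], [i], "k|", ms=14)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("Incremental net monetary benefit")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(points: Sequence[CEACPoint], wtp: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.probability for p in points], "-o", ms=3)
    ax.axvline(wtp, color="r", ls="--", lw=1, label=f"WTP = {wtp:g}/QALY")
    ax.set_xlabel("Willingness to pay per QALY")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
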
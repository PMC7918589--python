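"""Figure analogues: QoL trajectories, cost-effectiveness plane, CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .engine import BootstrapCloud, CEACCurve


def qol_plot(qol_table: pd.DataFrame, path: str | Path) -> None:
    """Mean utility per arm over the assessment grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, style in (("DN", "o-"), ("PNE", "s--")):
        ax.plot(qol_table["week"], qol_table[f"mean_{arm}"], style, label=arm)
    ax.set_xlabel("week")
    ax.set_ylabel("mean EQ-5D-5L utility")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(cloud: BootstrapCloud, path: str | Path) -> None:
    """Bootstrap (ΔE, ΔC) scatter with the plane axes."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(cloud.delta_qaly, cloud.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("incremental QALYs (PNE − DN)")
    ax.set_ylabel("incremental cost, € (PNE − DN)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: CEACCurve, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.thresholds, curve.probability)
    ax.set_xlabel("willingness to pay, €/QALY")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
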
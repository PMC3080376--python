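"""Time-course panels in the style of the simulation figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .simulation_engine import Trajectory  # noqa: E402

#: standard three-panel species layout used for the scenario figures
PANELS: tuple[tuple[str, ...], ...] = (
    ("NFkBn", "P_mRNA", "P"),
    ("pBim", "tBid", "Bcl2", "BaxBakA", "C3"),
    ("pJNK", "JNK", "ROS", "MKP", "MKPox"),
)


def plot_scenario(traj: Trajectory, title: str = "", path=None):
    """Three stacked panels: NF-kB arm, mitochondrial arm, JNK/ROS arm."""
    fig, axes = plt.subplots(len(PANELS), 1, figsize=(7, 9), sharex=True)
    for ax, names in zip(axes, PANELS):
        for n in names:
            ax.plot(traj.t, traj[n], label=n, lw=1.2)
        ax.legend(fontsize=7, ncol=3, frameon=False)
        ax.set_ylabel("amount")
    if traj.momp_time is not None:
        for ax in axes:
            ax.axvline(traj.momp_time, color="k", ls=":", lw=0.8)
    axes[-1].set_xlabel("time (h)")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_sensitivity_heatmap(result, path=None):
    """Heatmap of normalized local sensitivity coefficients."""
    df = result.to_frame()
    fig, ax = plt.subplots(figsize=(max(6, 0.16 * df.shape[1]), 2.5))
    vmax = max(1e-6, abs(df.to_numpy()).max())
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=7)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="d ln y / d ln p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
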
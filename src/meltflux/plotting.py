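"""Optional plotting hooks (requires matplotlib)."""

from __future__ import annotations

from .weeks import MONTH_NAMES


def scf_bar_panel(scf_table, path) -> None:
    """Bar panel of first-mode SCF per variable pair, one group per month."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    months = sorted(scf_table["month"].unique())
    fig, axes = plt.subplots(1, len(months), figsize=(4 * len(months), 3.2),
                             sharey=True)
    if len(months) == 1:
        axes = [axes]
    for ax, m in zip(axes, months):
        sub = scf_table[scf_table["month"] == m]
        ax.bar(sub["pair"], sub["scf1"], color="#4878a8")
        ax.set_title(MONTH_NAMES.get(m, str(m)))
        ax.set_ylim(0, 1)
        ax.tick_params(axis="x", rotation=60)
    axes[0].set_ylabel("first-mode SCF")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
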
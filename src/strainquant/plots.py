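"""Small plotting helpers for QC output (matplotlib, Agg backend)."""

from __future__ import annotations


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_count_curves(summary, path) -> None:
    """Mean ± SD object-count curves per condition over time."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for condition, sub in summary.groupby("condition"):
        sub = sub.sort_values("time_min")
        ax.errorbar(sub["time_min"], sub["mean"], yerr=sub["sd"].fillna(0.0),
                    marker="o", capsize=2, label=str(condition))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("objects per frame")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_scores(table, path, value_col: str = "normalized") -> None:
    """Per-group scatter of normalized enrichment scores with group means."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    groups = list(dict.fromkeys(table["group"]))
    for i, g in enumerate(groups):
        v = table.loc[table["group"] == g, value_col]
        ax.scatter([i] * len(v), v, s=14, alpha=0.7)
        ax.hlines(v.mean(), i - 0.25, i + 0.25, color="k")
    ax.set_xticks(range(len(groups)), groups, rotation=30, ha="right")
    ax.set_ylabel("normalized enrichment score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
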
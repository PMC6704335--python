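"""Horizontal-bar exports for signature and importance rankings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

GROUP_COLORS = {"Vata": "#1b9e77", "Pitta": "#d95f02", "Kapha": "#7570b3"}


def plot_lda_scores(records, path, title: str = "LDA scores") -> None:
    """Horizontal bars of log10 LDA scores, colored by enriched group."""
    records = sorted(records, key=lambda r: r.lda_score)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(records) + 1)))
    names = [r.function_id for r in records]
    scores = [r.lda_score for r in records]
    colors = [GROUP_COLORS.get(r.enriched_group, "grey") for r in records]
    ax.barh(names, scores, color=colors)
    ax.axvline(2.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xlabel("log10 LDA score")
    ax.set_title(title)
    handles = [plt.Rectangle((0, 0), 1, 1, color=c)
               for c in GROUP_COLORS.values()]
    ax.legend(handles, GROUP_COLORS.keys(), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(result, path, title: str = "Mean decrease accuracy") -> None:
    """Horizontal bars of mean-decrease-accuracy importances."""
    ranking = result.ranking.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(ranking) + 1)))
    ax.barh(ranking["feature"], ranking["importance"], color="#386cb0")
    ax.set_xlabel("mean decrease in OOB accuracy")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_oob_error_curve(result, path, title: str = "OOB error") -> None:
    """Out-of-bag error as the ensemble grows."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(result.oob_curve["n_trees"], result.oob_curve["oob_error"])
    ax.set_xlabel("number of trees")
    ax.set_ylabel("OOB error")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
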
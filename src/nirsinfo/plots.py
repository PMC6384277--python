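"""Optional study figures: lag curve, criterion distributions, margins."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .study import SETTINGS, StudyReport

__all__ = ["plot_lag_curve", "plot_criterion", "plot_margins", "save_all"]


def plot_lag_curve(report: StudyReport, ax=None):
    ax = ax or plt.gca()
    ax.plot(report.lag_grid, report.mean_lag_curve, lw=1.5)
    ax.axvline(report.study_lag, color="crimson", ls="--", lw=1,
               label=f"study lag = {report.study_lag}")
    ax.set_xlabel("lag (samples)")
    ax.set_ylabel("grand-average TE (nats)")
    ax.legend(frameon=False)
    return ax


def plot_criterion(report: StudyReport, quantity: str, ax=None):
    ax = ax or plt.gca()
    data = [report.per_round[name][quantity] for name in SETTINGS]
    ax.boxplot(data, tick_labels=list(SETTINGS))
    ax.set_ylabel(f"{quantity} (nats)")
    return ax


def plot_margins(report: StudyReport, ax=None):
    return plot_criterion(report, "c5_margin", ax=ax)


def save_all(report: StudyReport, outdir) -> list[str]:
    import os

    written = []
    for name, fn in (
        ("lag_curve", plot_lag_curve),
        ("te_after", lambda r, ax: plot_criterion(r, "te_after", ax)),
        ("c5_margin", plot_margins),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        fn(report, ax)
        fig.tight_layout()
        path = os.path.join(outdir, f"{name}.png")
        fig.savefig(path, dpi=130)
        plt.close(fig)
        written.append(path)
    return written
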
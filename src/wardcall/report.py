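"""Result tables, arrival-curve series and comparison reports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .simulate import Metrics, arrival_histogram, summarize_comparison


def render_workload_table(metrics: Metrics) -> pd.DataFrame:
    """Workload distribution keyed by nurse count.

    One row per number of nurses present, columns Max., Min., # 0% and
    Std. Err. (population standard deviation of per-nurse call
    percentages), averaged over the runs with that nurse count.
    """
    per_run = metrics.workload_summary()
    if per_run.empty:
        return pd.DataFrame(columns=["n_nurses", "max", "min", "n_zero", "std"])
    table = (
        per_run.groupby("n_nurses")[["max", "min", "n_zero", "std"]]
        .mean()
        .reset_index()
        .sort_values("n_nurses")
        .reset_index(drop=True)
    )
    return table.round(2)


def render_arrival_curves(metrics: Metrics, by: Optional[str] = None) -> pd.DataFrame:
    """Per-bin and cumulative arrival-time series.

    Bins are 5 s wide up to 60 s and 60 s wide beyond, mirroring the
    two-regime axis of the arrival-time figures. Returns a tidy frame with
    ``group, bin_start, bin_end, count, cumulative``.
    """
    hist = arrival_histogram(metrics.arrival_delays, by=by)
    if hist.empty:
        hist["cumulative"] = pd.Series(dtype=float)
        return hist
    hist = hist.copy()
    hist["cumulative"] = hist.groupby("group")["count"].cumsum()
    return hist


def plot_arrival_curves(metrics: Metrics, path, by: Optional[str] = None) -> None:
    """Optional matplotlib rendering of the arrival curves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = render_arrival_curves(metrics, by=by)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    for group, grp in curves.groupby("group"):
        ax.step(grp["bin_start"], grp["cumulative"], where="post", label=str(group))
    ax.axvline(60, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xlabel("nurse arrival time (s)")
    ax.set_ylabel("calls with a nurse present (cumulative)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ComparisonReport:
    """Paired policy comparison with a reproducibility manifest."""

    person: Metrics
    place: Metrics
    manifest: dict

    @property
    def summary(self) -> dict:
        return summarize_comparison(self.person, self.place)

    def workload_tables(self) -> dict:
        return {
            "person": render_workload_table(self.person),
            "place": render_workload_table(self.place),
        }
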
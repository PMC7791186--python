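"""Plotting helpers for prediction fields and cohort trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_field(field_csv, out_png=None, ax=None):
    """Plot an exported prediction field: main paths in red, folds in grey.

    Accepts the tidy CSV written by :func:`growthsde.predict.export_field`.
    """
    from .predict import read_field

    df = read_field(field_csv) if not isinstance(field_csv, pd.DataFrame) else field_csv
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for (sa, sv, kind), grp in df.groupby(
        ["start_age", "start_value", "path_kind"], sort=False
    ):
        if kind == "main":
            ax.plot(grp["age"], grp["predicted_value"], color="crimson", lw=0.8, zorder=3)
        else:
            ax.plot(grp["age"], grp["predicted_value"], color="grey", lw=0.3, alpha=0.5)
    ax.set_xlabel("age (months)")
    ax.set_ylabel("weight-for-length z-score")
    ax.set_title("Predicted growth trajectories")
    if out_png:
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
    return ax


def plot_cohort(cohort_frame, out_png=None, ax=None):
    """Spaghetti plot of trajectories with per-site monthly means."""
    df = cohort_frame
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for _, grp in df.groupby("child_id"):
        ax.plot(grp["age_months"], grp["zwfl"], color="grey", lw=0.3, alpha=0.4)
    for site, grp in df.groupby("site"):
        month = grp["age_months"].round()
        means = grp.groupby(month)["zwfl"].mean()
        ax.plot(means.index, means.values, lw=2, label=str(site))
    ax.set_xlabel("age (months)")
    ax.set_ylabel("weight-for-length z-score")
    ax.legend()
    if out_png:
        ax.figure.savefig(out_png, dpi=150, bbox_inches="tight")
    return ax
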
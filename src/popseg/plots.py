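"""Optional plots: segment means with CI bars and a dashed overall-rate line.

Requires matplotlib (install the ``plots`` extra); imported lazily so the
rest of the package works without it.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

_TITLES = {
    "eq5d": "Health utility (EQ-5D index) by segment",
    "mortality": "Mortality probability by segment",
    "admissions": "Mean hospital admissions by segment",
    "ed": "Mean ED visits by segment",
    "soc": "Mean SOC visits by segment",
}


def plot_outcome_by_segment(table: pd.DataFrame, outcome: str):
    """One figure per outcome: a panel per scheme, CI bars, dashed overall line.

    ``table`` is the corresponding DataFrame from
    :func:`popseg.stats.build_validity_report` (or the ``eq5d`` summary).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    value_col = "mean_eq5d" if outcome == "eq5d" else "mean"
    schemes = sorted(table["scheme"].unique())
    fig, axes = plt.subplots(1, len(schemes), figsize=(4 * len(schemes), 3.2),
                             sharey=True, squeeze=False)
    for ax, scheme in zip(axes[0], schemes):
        group = table[table["scheme"] == scheme]
        overall = group[group["segment_label"] == "(all subjects)"]
        segments = group[group["segment_label"] != "(all subjects)"].sort_values("segment_id")
        x = range(len(segments))
        if "ci_low" in segments.columns:
            yerr = [segments[value_col] - segments["ci_low"],
                    segments["ci_high"] - segments[value_col]]
            ax.errorbar(x, segments[value_col], yerr=yerr, fmt="o", capsize=3)
        else:
            ax.plot(x, segments[value_col], "o")
        if not overall.empty:
            ax.axhline(overall[value_col].iloc[0], linestyle="--", linewidth=1)
        ax.set_xticks(list(x))
        ax.set_xticklabels(segments["segment_id"].astype(int), fontsize=7)
        ax.set_title(scheme, fontsize=9)
        ax.set_xlabel("segment")
    axes[0][0].set_ylabel(_TITLES[outcome])
    fig.suptitle(_TITLES[outcome])
    fig.tight_layout()
    return fig


def save_report_plots(tables: Mapping[str, pd.DataFrame], out_dir) -> list:
    """Write fig1..fig5 PNG analogues; returns the paths written."""
    from pathlib import Path

    names = {"eq5d": "fig1_eq5d", "mortality": "fig2_mortality",
             "admissions": "fig3_admissions", "ed": "fig4_ed", "soc": "fig5_soc"}
    written = []
    for outcome, stem in names.items():
        if outcome not in tables:
            continue
        fig = plot_outcome_by_segment(tables[outcome], outcome)
        path = Path(out_dir) / f"{stem}.png"
        fig.savefig(path, dpi=120)
        written.append(str(path))
        import matplotlib.pyplot as plt

        plt.close(fig)
    return written
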
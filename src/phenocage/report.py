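"""Figure and table generation for a scored study.

Every figure panel is backed by a TSV written next to it, so plotted
values can always be checked against the underlying table; rendering is
deterministic (fixed figure sizes, no timestamps in metadata) and group
summaries are presented as mean +/- standard deviation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as pio
from .cognitionwall import km_survival

__all__ = ["mean_sd_table", "make_report"]

GROUP_ORDER = ("wildtype_male", "mdx_male", "wildtype_female", "mdx_female")


def _ordered(groups):
    known = [g for g in GROUP_ORDER if g in groups]
    rest = [g for g in groups if g not in GROUP_ORDER]
    return known + sorted(rest)


def mean_sd_table(values_by_group: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for g in _ordered(values_by_group):
        v = np.asarray(values_by_group[g], float)
        v = v[np.isfinite(v)]
        rows.append({"group": g, "n": len(v),
                     "mean": float(v.mean()) if len(v) else np.nan,
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan})
    return pd.DataFrame(rows)


def _km_figure(tables: Dict[str, pd.DataFrame], title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for g in _ordered(tables):
        t = tables[g]
        ax.step(t["entries"], t["fraction_remaining"], where="post", label=g)
    ax.set_xlabel("entries")
    ax.set_ylabel("fraction not at criterion")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)


def _bar_figure(table: pd.DataFrame, ylabel: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.0, 3.2))
    x = np.arange(len(table))
    ax.bar(x, table["mean"], yerr=table["sd"].fillna(0.0), capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(table["group"], rotation=30, ha="right", fontsize=7)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)


def make_report(results: Mapping, out_dir) -> Dict:
    """Render tables and figures for whichever results are supplied.

    Recognised keys:

    ``criterion_dl`` / ``criterion_rl``
        dict group -> list of :class:`~phenocage.core.CriterionResult`;
        rendered as Kaplan-Meier step tables and plots.
    ``rl_errors``
        subject-level error table (genotype, sex, day, perseverative,
        neutral); rendered as per group x day mean +/- SD tables and bars.
    ``alternation``, ``total_arm_entries``, ``dlb_latency``,
    ``dlb_time_in_light``, ``dlb_visits``, ``activity_entries``,
    ``activity_distance_m``
        dict group -> values; rendered as mean +/- SD tables and bar plots.

    Empty input produces an empty report with a valid manifest.  Returns
    the manifest of written tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: Dict[str, pd.DataFrame] = {}

    for key, title in (("criterion_dl", "DL criterion"),
                       ("criterion_rl", "RL criterion")):
        if key in results:
            km = km_survival(results[key])
            combined = pd.concat(
                [t.assign(group=g) for g, t in km.items()], ignore_index=True
            )[["group", "entries", "fraction_remaining"]]
            tables[f"{key}_km"] = combined
            _km_figure(km, title, out / f"{key}_km.png")

    if "rl_errors" in results:
        err = pd.DataFrame(results["rl_errors"])
        for measure in ("perseverative", "neutral"):
            if measure not in err.columns:
                continue
            grp = (err.assign(group=err["genotype"] + "_" + err["sex"])
                      .groupby(["group", "day"], observed=True)[measure]
                      .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
                      .reset_index())
            tables[f"rl_errors_{measure}"] = grp

    for key in ("alternation", "total_arm_entries", "dlb_latency",
                "dlb_time_in_light", "dlb_visits", "activity_entries",
                "activity_distance_m"):
        if key in results:
            table = mean_sd_table(results[key])
            tables[key] = table
            _bar_figure(table, key.replace("_", " "), out / f"{key}.png")

    return pio.write_results(tables, out)
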
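"""Mitotic timing, arrest tabulation, and group-comparison reporting.

Timing rule: per-cell duration is (anaphase frame − NEB frame) × frame
interval.  A cell that enters mitosis but never reaches anaphase is
scored *arrested* ("never divides") only when at least one hour of movie
remained after NEB; with less than an hour remaining it is *censored* and
excluded from both the duration and the arrest tabulation.

Statistics are a thin reporting stage over standard routines: one-way
ANOVA with Tukey's HSD (parametric family) or Kruskal–Wallis with Dunn's
all-pairs rank test (nonparametric family; Holm-adjusted — the adjustment
flavor is a package choice).  Per-replicate means are emitted alongside
per-cell values for superplot-style reporting, but tests run on per-cell
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io import validate_event_table, validate_group_table

__all__ = [
    "TimingResult",
    "ComparisonReport",
    "mitotic_timing",
    "compare_groups",
    "dunn_test",
]

ARREST_WINDOW_MIN = 60.0  # "at least one hour prior to the movie end"


@dataclass
class TimingResult:
    """Per-cell mitotic timing plus the arrest tabulation."""

    per_cell: pd.DataFrame          # cell_id, status, duration_min
    median_duration_min: float
    arrest_fraction_pct: float
    n_divided: int
    n_arrested: int
    n_censored: int

    @property
    def n_total(self) -> int:
        return self.n_divided + self.n_arrested + self.n_censored


def mitotic_timing(events: pd.DataFrame,
                   frame_interval_min: float) -> TimingResult:
    """Score NEB→anaphase durations and never-divide arrest.

    ``events`` needs columns cell_id, neb_frame, anaphase_frame (NaN when
    the event was not observed) and movie_end_frame.  A row with anaphase
    but no NEB is an error; a row with neither is ignored (the cell never
    entered mitosis).
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    ev = validate_event_table(events)
    rows = []
    for r in ev.itertuples(index=False):
        has_neb = not pd.isna(r.neb_frame)
        has_ao = not pd.isna(r.anaphase_frame)
        if has_ao and not has_neb:
            raise ValueError(
                f"cell {r.cell_id}: anaphase recorded without NEB")
        if not has_neb:
            continue
        if has_ao:
            dur = (r.anaphase_frame - r.neb_frame) * frame_interval_min
            rows.append((r.cell_id, "divided", float(dur)))
        else:
            remaining = (r.movie_end_frame - r.neb_frame) * frame_interval_min
            status = ("arrested" if remaining >= ARREST_WINDOW_MIN
                      else "censored")
            rows.append((r.cell_id, status, np.nan))
    per_cell = pd.DataFrame(rows,
                            columns=["cell_id", "status", "duration_min"])
    n_div = int((per_cell["status"] == "divided").sum())
    n_arr = int((per_cell["status"] == "arrested").sum())
    n_cen = int((per_cell["status"] == "censored").sum())
    durations = per_cell.loc[per_cell["status"] == "divided", "duration_min"]
    median = float(durations.median()) if n_div else float("nan")
    denom = n_div + n_arr
    arrest = 100.0 * n_arr / denom if denom else float("nan")
    return TimingResult(per_cell, median, arrest, n_div, n_arr, n_cen)


# ---------------------------------------------------------------------------
# group comparisons

@dataclass
class ComparisonReport:
    """Omnibus test plus all-pairs adjusted comparisons for one metric."""

    metric: str
    family: str                      # "parametric" | "nonparametric"
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame           # group1, group2, stat, p_adj
    summary: pd.DataFrame            # per condition: n, mean, median, sd
    replicate_means: pd.DataFrame    # per (condition, replicate): n, mean


def dunn_test(groups: dict[str, np.ndarray],
              adjust: str = "holm") -> pd.DataFrame:
    """Dunn's all-pairs rank comparison after Kruskal–Wallis.

    z-statistic on mean ranks with tie correction; two-sided normal
    p-values adjusted by ``adjust`` (statsmodels method name).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float)
                             for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(values)
    ranks = stats.rankdata(values)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    # tie correction: 1 − Σ(t³ − t) / (n³ − n)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - float(((counts ** 3 - counts).sum()) / (n ** 3 - n))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(n * (n + 1) / 12.0 * tie *
                         (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, float(z), float(p)))
    df = pd.DataFrame(rows, columns=["group1", "group2", "stat", "p_raw"])
    df["p_adj"] = multipletests(df["p_raw"], method=adjust)[1]
    return df.drop(columns="p_raw")


def compare_groups(table: pd.DataFrame, metric: str,
                   family: str = "parametric",
                   min_group_size: int = 3) -> ComparisonReport:
    """All-pairs comparison of one metric across conditions.

    ``family="parametric"`` → one-way ANOVA + Tukey HSD;
    ``family="nonparametric"`` → Kruskal–Wallis + Dunn (Holm-adjusted).
    Requires ≥ 2 conditions with ≥ ``min_group_size`` cells each.
    """
    if family not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown family {family!r}")
    table = validate_group_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    groups = {c: g["value"].to_numpy(dtype=float)
              for c, g in sub.groupby("condition", sort=False)}
    if len(groups) < 2:
        raise ValueError("need ≥ 2 conditions to compare")
    small = {c: len(v) for c, v in groups.items() if len(v) < min_group_size}
    if small:
        raise ValueError(f"groups below n={min_group_size}: {small}")
    if family == "parametric":
        stat, p = stats.f_oneway(*groups.values())
        tk = pairwise_tukeyhsd(sub["value"].to_numpy(dtype=float),
                               sub["condition"].to_numpy(),
                               alpha=0.05)
        tab = np.asarray(tk._results_table.data[1:], dtype=object)
        pairwise = pd.DataFrame({
            "group1": tab[:, 0], "group2": tab[:, 1],
            "stat": tk.meandiffs, "p_adj": tk.pvalues,
        })
    else:
        stat, p = stats.kruskal(*groups.values())
        pairwise = dunn_test(groups)
    summary = (sub.groupby("condition")["value"]
               .agg(n="count", mean="mean", median="median", sd="std")
               .reset_index())
    reps = (sub.groupby(["condition", "replicate"])["value"]
            .agg(n="count", mean="mean")
            .reset_index())
    return ComparisonReport(metric=metric, family=family,
                            omnibus_stat=float(stat), omnibus_p=float(p),
                            pairwise=pairwise, summary=summary,
                            replicate_means=reps)
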
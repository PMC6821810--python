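"""Proliferation time courses: assembly, doubling time, chamber cross-check.

Cell-count estimates from independent replicate lines are grouped per
culture condition, aligned on sampling days, and summarised as mean ± SD
across lines (sample SD, n−1 denominator — the convention for three
independent biological replicates).  Doubling times come from a log-linear
ordinary-least-squares fit, and estimates can be cross-validated against
direct hemocytometer (counting-chamber) counts via per-pair ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

from .exceptions import (
    EmptyInputError,
    InsufficientDataError,
    InvalidSeriesError,
    PairingError,
)

#: Sentinel doubling time for a non-growing (zero or negative slope) series.
NON_GROWING = math.inf


@dataclass(frozen=True)
class GrowthSeries:
    """One condition's time course across replicate lines.

    ``per_line_cells`` maps each line to a list aligned with ``days``
    (``nan`` where that line was not sampled).  ``sd_cells`` is the sample
    SD across contributing lines, ``nan`` whenever fewer than two lines
    contribute at a day; such days are listed in ``partial_days``.
    """

    condition: str
    days: tuple[int, ...]
    per_line_cells: dict
    mean_cells: tuple[float, ...]
    sd_cells: tuple[float, ...]
    partial_days: tuple[int, ...] = ()

    def line_values(self, line: str) -> np.ndarray:
        return np.asarray(self.per_line_cells[line], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "day": self.days,
                "mean_cells": self.mean_cells,
                "sd_cells": self.sd_cells,
            }
        )


def assemble_timecourse(estimates: pd.DataFrame) -> list[GrowthSeries]:
    """Group an estimates table into per-condition growth series.

    Parameters
    ----------
    estimates : DataFrame
        Needs columns ``condition``, ``line``, ``day`` and ``cells``; when a
        ``status`` column is present only ``ok`` rows are used.  Repeated
        (condition, line, day) measurements are averaged.
    """
    required = {"condition", "line", "day", "cells"}
    if not required.issubset(estimates.columns):
        missing = sorted(required - set(estimates.columns))
        raise EmptyInputError(f"estimates table lacks columns: {missing}")
    df = estimates
    if "status" in df.columns:
        df = df[df["status"] == "ok"]
    df = df[np.isfinite(df["cells"])]
    if df.empty:
        raise EmptyInputError("no usable (status-ok, finite) rows in estimates table")

    series: list[GrowthSeries] = []
    for condition, grp in df.groupby("condition", sort=True):
        wide = grp.pivot_table(index="day", columns="line", values="cells", aggfunc="mean")
        wide = wide.sort_index()
        values = wide.to_numpy(dtype=float)
        n_lines = np.sum(~np.isnan(values), axis=1)
        mean = np.nanmean(values, axis=1)
        sd = np.array(
            [np.nanstd(row, ddof=1) if n >= 2 else np.nan for row, n in zip(values, n_lines)]
        )
        days = tuple(int(d) for d in wide.index)
        partial = tuple(
            int(d) for d, n in zip(wide.index, n_lines) if n < values.shape[1]
        )
        series.append(
            GrowthSeries(
                condition=str(condition),
                days=days,
                per_line_cells={str(c): list(wide[c].to_numpy()) for c in wide.columns},
                mean_cells=tuple(float(m) for m in mean),
                sd_cells=tuple(float(s) for s in sd),
                partial_days=partial,
            )
        )
    return series


def doubling_time(series: GrowthSeries, line: Optional[str] = None) -> float:
    """Population doubling time from a log-linear fit, in days.

    Ordinary least squares of ``ln(cells)`` on day, over the selected line's
    counts (or the cross-line mean when ``line`` is None); doubling time is
    ``ln 2 / slope``.  Returns :data:`NON_GROWING` (``inf``) when the slope
    is not positive.  Two points reduce OLS to the exact closed form.
    """
    values = (
        np.asarray(series.mean_cells, dtype=float)
        if line is None
        else series.line_values(line)
    )
    days = np.asarray(series.days, dtype=float)
    mask = ~np.isnan(values)
    values, days = values[mask], days[mask]
    if values.size < 2:
        raise InsufficientDataError("need >= 2 time points for a doubling time")
    if np.any(values <= 0):
        raise InvalidSeriesError("doubling time requires strictly positive cell counts")
    slope = linregress(days, np.log(values)).slope
    if slope <= 0:
        return NON_GROWING
    return float(math.log(2) / slope)


@dataclass(frozen=True)
class ChamberComparison:
    """Paired comparison of DNAm-based estimates against chamber counts.

    ``ratios`` are estimated/chamber per matched (condition, line, day)
    pair; the assay and the hemocytometer are declared to agree
    (``similar_range``) when every ratio falls inside ``band``.
    ``pearson_r`` is reported only with >= 3 pairs.
    """

    pairs: pd.DataFrame
    ratios: tuple[float, ...]
    pearson_r: Optional[float]
    band: tuple[float, float]
    similar_range: bool


def compare_chamber_counts(
    estimates: pd.DataFrame,
    chamber: pd.DataFrame,
    band: tuple[float, float] = (1.0 / 3.0, 3.0),
) -> ChamberComparison:
    """Cross-validate estimates against direct counting-chamber counts.

    Both tables need ``condition``, ``line``, ``day`` plus a count column
    (``cells`` in ``estimates``, ``chamber_cells`` — or ``cells`` — in
    ``chamber``); rows are matched on the three keys.
    """
    keys = ["condition", "line", "day"]
    est = estimates.copy()
    cha = chamber.copy()
    if "chamber_cells" not in cha.columns:
        cha = cha.rename(columns={"cells": "chamber_cells"})
    for df, col in ((est, "cells"), (cha, "chamber_cells")):
        need = set(keys + [col])
        if not need.issubset(df.columns):
            raise PairingError(f"table lacks columns {sorted(need - set(df.columns))}")
    merged = est.merge(cha[keys + ["chamber_cells"]], on=keys, how="inner")
    if "status" in merged.columns:
        merged = merged[merged["status"] == "ok"]
    merged = merged[(merged["cells"] > 0) & (merged["chamber_cells"] > 0)]
    if merged.empty:
        raise PairingError("no matched (condition, line, day) pairs with positive counts")
    ratios = (merged["cells"] / merged["chamber_cells"]).to_numpy(dtype=float)
    r = None
    if len(merged) >= 3 and merged["cells"].nunique() > 1 and merged["chamber_cells"].nunique() > 1:
        r = float(pearsonr(merged["cells"], merged["chamber_cells"]).statistic)
    lo, hi = band
    return ChamberComparison(
        pairs=merged[keys + ["cells", "chamber_cells"]].reset_index(drop=True),
        ratios=tuple(float(x) for x in ratios),
        pearson_r=r,
        band=(float(lo), float(hi)),
        similar_range=bool(np.all((ratios >= lo) & (ratios <= hi))),
    )


def plot_timecourse(series: Sequence[GrowthSeries], path: Optional[str] = None):
    """Plot mean ± SD growth curves per condition (log-scale cell axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series:
        mean = np.asarray(s.mean_cells)
        sd = np.nan_to_num(np.asarray(s.sd_cells))
        ax.errorbar(s.days, mean, yerr=sd, marker="o", capsize=3, label=s.condition)
    ax.set_yscale("log")
    ax.set_xlabel("day of differentiation")
    ax.set_ylabel("estimated cells")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
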
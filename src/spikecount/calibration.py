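"""Calibration of pure-component levels and mixing-series validation.

``fit_calibration`` estimates the pure-plasmid (``a``) and pure-genomic
(``b``) methylation levels from control measurements.
``validate_mixing_series`` replays the assay's standard-curve experiment:
known cell numbers mixed with a fixed spike amount, measured methylation
correlated against truth, and per-point estimation errors summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .core import CalibrationParams, MixtureContext
from .estimator import GENOMIC, PLASMID, SpikeInCellCounter, counter_from_context
from .exceptions import InsufficientDataError, InvalidMeasurementError


def fit_calibration(
    pure_plasmid_dnam: Sequence[float],
    pure_genomic_dnam: Sequence[float],
    depths: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> CalibrationParams:
    """Estimate a and b as (optionally depth-weighted) means of controls.

    Raises a calibration-separation error when the plasmid mean does not lie
    strictly below the genomic mean (swapped or unusable controls).
    """
    plasmid = np.asarray(list(pure_plasmid_dnam), dtype=float)
    genomic = np.asarray(list(pure_genomic_dnam), dtype=float)
    if plasmid.size == 0 or genomic.size == 0:
        raise InsufficientDataError("both control lists must be non-empty")
    for arr in (plasmid, genomic):
        if arr.min() < 0 or arr.max() > 1:
            raise InvalidMeasurementError("control DNAm values must lie in [0, 1]")
    X = np.concatenate([plasmid, genomic])
    y = np.array([PLASMID] * plasmid.size + [GENOMIC] * genomic.size, dtype=object)
    w = None
    weighted = depths is not None
    if weighted:
        w = np.concatenate([np.asarray(depths[0], float), np.asarray(depths[1], float)])
    counter = SpikeInCellCounter(copies=1.0, depth_weighted=weighted).fit(X, y, sample_weight=w)
    return counter.calibration_


@dataclass(frozen=True)
class ValidationReport:
    """Summary of a mixing-series validation run.

    ``pearson_r_dnam_vs_cells`` is the calibration-curve statistic (measured
    methylation against true cell number, per-mixture replicate means);
    ``pearson_r_est_vs_true`` correlates the inverted estimates with truth,
    which is the linear relation whenever the model holds.  Error statistics
    cover status-ok rows only; clamped/saturated rows are counted.
    """

    pearson_r_dnam_vs_cells: float
    pearson_r_est_vs_true: float
    per_point_relative_error: tuple[float, ...]
    median_relative_error: float
    n_points: int
    n_clamped: int = 0
    n_saturated: int = 0
    log_scale: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_point_relative_error"] = list(d["per_point_relative_error"])
        return d


def validate_mixing_series(
    measurements: pd.DataFrame,
    ctx: MixtureContext,
    log_cells: bool = False,
) -> ValidationReport:
    """Validate the estimator against a mixing series with known truth.

    Parameters
    ----------
    measurements : DataFrame
        Must carry ``dnam`` and ``true_cells`` columns (the simulator's
        output format, or a measured series with truth attached).
    ctx : MixtureContext
        Copy number, calibration and ploidy used for inversion.
    log_cells : bool
        Correlate against log10 cell numbers instead of raw counts
        (raw is the default reading of the assay's published statistic).
    """
    if not {"dnam", "true_cells"}.issubset(measurements.columns):
        raise InsufficientDataError("measurements need 'dnam' and 'true_cells' columns")
    df = measurements.copy()
    if df["true_cells"].nunique() < 3:
        raise InsufficientDataError(
            "need >= 3 distinct true cell numbers to validate a series"
        )

    counter = counter_from_context(ctx)
    ests = counter.estimate(df["dnam"].to_numpy())
    df["est_cells"] = [e.cells for e in ests]
    df["status"] = [e.status.value for e in ests]

    ok = df[df["status"] == "ok"]
    if ok["true_cells"].nunique() < 3:
        raise InsufficientDataError("fewer than 3 usable (status-ok) points")

    def _xform(c: np.ndarray) -> np.ndarray:
        return np.log10(c) if log_cells else c

    # calibration-curve statistic on per-mixture replicate means
    per_point = df.groupby("true_cells", sort=True)["dnam"].mean()
    r_dnam = float(pearsonr(per_point.to_numpy(), _xform(per_point.index.to_numpy())).statistic)
    r_est = float(pearsonr(ok["est_cells"].to_numpy(), _xform(ok["true_cells"].to_numpy())).statistic)

    rel_err = (
        np.abs(ok["est_cells"].to_numpy() - ok["true_cells"].to_numpy())
        / np.maximum(ok["true_cells"].to_numpy(), 1.0)
    )
    return ValidationReport(
        pearson_r_dnam_vs_cells=r_dnam,
        pearson_r_est_vs_true=r_est,
        per_point_relative_error=tuple(float(e) for e in rel_err),
        median_relative_error=float(np.median(rel_err)),
        n_points=int(df["true_cells"].nunique()),
        n_clamped=int((df["status"] == "clamped_below").sum()),
        n_saturated=int((df["status"] == "saturated").sum()),
        log_scale=bool(log_cells),
    )
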
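"""Scikit-learn style estimator wrapping the spike-in mixture inversion.

:class:`SpikeInCellCounter` is the package's central surface: calibrate the
pure-component methylation levels on control measurements with :meth:`fit`,
then turn methylation readouts into absolute cell counts with
:meth:`predict`.  It follows the scikit-learn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``check_is_fitted`` semantics) and composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import core
from .core import (
    CalibrationParams,
    CalibrationSource,
    CellEstimate,
    EstimateStatus,
    MixtureContext,
    SpikeInLocus,
)
from .exceptions import (
    CalibrationSeparationError,
    InsufficientDataError,
    InvalidMeasurementError,
)

PLASMID = "plasmid"
GENOMIC = "genomic"


def _as_dnam_vector(X) -> np.ndarray:
    """Coerce input to a 1-D float vector of methylation fractions."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise InvalidMeasurementError(
            f"expected a 1-D array (or single-column matrix) of DNAm fractions, "
            f"got shape {np.shape(X)}"
        )
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        bad = arr[(arr < 0) | (arr > 1)][0]
        raise InvalidMeasurementError(f"DNAm values must lie in [0, 1], got {bad}")
    return arr


class SpikeInCellCounter(BaseEstimator):
    """Absolute cell counting from spike-in methylation readouts.

    The measurement model: a sample's DNA extract carries ``ploidy`` fully
    methylated target alleles per cell plus ``copies`` non-methylated
    reference-plasmid molecules; the observed methylation fraction is the
    copy-weighted mean of the pure-component levels ``b`` (genomic) and
    ``a`` (plasmid).  Fitting estimates ``a`` and ``b`` as means of control
    measurements; prediction inverts the mixture.

    Parameters
    ----------
    locus : SpikeInLocus, optional
        Spike-in amplicon; its mass, molar weight and correction factor fix
        the reference copy number.  Default: the shipped LSM14B amplicon.
    copies : float, optional
        Explicit reference copy number; overrides ``locus`` when given.
    ploidy : int, default 2
        Genomic target alleles per cell.
    a, b : float, optional
        Explicit pure-component methylation levels.  When both are given,
        :meth:`fit` accepts no control data and simply freezes them.
    depth_weighted : bool, default False
        Weight control measurements by read depth (``sample_weight`` in
        :meth:`fit`) instead of the unweighted mean.

    Attributes
    ----------
    a_ : float
        Fitted pure-plasmid methylation level.
    b_ : float
        Fitted pure-genomic methylation level.
    calibration_ : CalibrationParams
        The fitted calibration (``source`` records whether it was fitted
        from controls or taken from explicit/default levels).
    copies_ : float
        Reference copy number used for inversion.
    context_ : MixtureContext
        The full mixture context assembled at fit time.

    Examples
    --------
    >>> counter = SpikeInCellCounter(copies=1000, a=0.0, b=1.0).fit()
    >>> counter.predict([0.5])
    array([500.])
    """

    def __init__(
        self,
        locus: Optional[SpikeInLocus] = None,
        copies: Optional[float] = None,
        ploidy: int = 2,
        a: Optional[float] = None,
        b: Optional[float] = None,
        depth_weighted: bool = False,
    ):
        self.locus = locus
        self.copies = copies
        self.ploidy = ploidy
        self.a = a
        self.b = b
        self.depth_weighted = depth_weighted

    # ------------------------------------------------------------------ fit

    def fit(self, X=None, y=None, sample_weight=None) -> "SpikeInCellCounter":
        """Calibrate pure-component levels and freeze the mixture context.

        Parameters
        ----------
        X : array-like of shape (n,) or (n, 1), optional
            Methylation fractions of pure-component control measurements.
        y : array-like of str, optional
            Label per control row: ``"plasmid"`` for pure reference DNA,
            ``"genomic"`` for pure genomic DNA.  Required when ``X`` is
            given.
        sample_weight : array-like, optional
            Per-row weights (typically read depths) used when
            ``depth_weighted=True``.
        """
        if X is None:
            a = 0.0 if self.a is None else float(self.a)
            b = 1.0 if self.b is None else float(self.b)
            source = (
                CalibrationSource.DEFAULT
                if self.a is None and self.b is None
                else CalibrationSource.FITTED
            )
            self.calibration_ = CalibrationParams(a, b, source)
        else:
            if y is None:
                raise InsufficientDataError(
                    "control labels y ('plasmid'/'genomic') are required with X"
                )
            dnam = _as_dnam_vector(X)
            labels = np.asarray(y, dtype=object)
            if labels.shape != dnam.shape:
                raise InsufficientDataError("X and y must have the same length")
            plasmid = dnam[labels == PLASMID]
            genomic = dnam[labels == GENOMIC]
            if plasmid.size == 0 or genomic.size == 0:
                raise InsufficientDataError(
                    "need at least one 'plasmid' and one 'genomic' control"
                )
            if self.depth_weighted and sample_weight is not None:
                w = np.asarray(sample_weight, dtype=float)
                a = float(np.average(plasmid, weights=w[labels == PLASMID]))
                b = float(np.average(genomic, weights=w[labels == GENOMIC]))
            else:
                a = float(plasmid.mean())
                b = float(genomic.mean())
            if a >= b:
                raise CalibrationSeparationError(
                    f"mean plasmid level ({a:.4g}) is not below mean genomic "
                    f"level ({b:.4g}); controls swapped or unusable"
                )
            self.calibration_ = CalibrationParams(a, b, CalibrationSource.FITTED)

        self.a_ = self.calibration_.a
        self.b_ = self.calibration_.b
        self.copies_ = (
            float(self.copies)
            if self.copies is not None
            else core.reference_copy_number(self.locus if self.locus is not None else core.LSM14B)
        )
        self.context_ = MixtureContext(self.copies_, self.calibration_, int(self.ploidy))
        return self

    # -------------------------------------------------------------- predict

    def estimate(self, X) -> list[CellEstimate]:
        """Full per-measurement estimates including status flags."""
        self._check_fitted()
        return [core.estimate_cells(d, self.context_) for d in _as_dnam_vector(X)]

    def predict(self, X) -> np.ndarray:
        """Cell counts for methylation readouts ``X``.

        Clamped rows (DNAm <= a) yield 0; saturated rows (DNAm >= b) yield
        ``inf``.  Use :meth:`estimate` or :meth:`predict_status` to
        distinguish them from valid interior estimates.
        """
        return np.array([e.cells for e in self.estimate(X)], dtype=float)

    def predict_status(self, X) -> np.ndarray:
        """Status string (``ok``/``clamped_below``/``saturated``) per row."""
        return np.array([e.status.value for e in self.estimate(X)], dtype=object)

    def forward(self, cells) -> np.ndarray:
        """Expected methylation for given cell numbers (model forward pass)."""
        self._check_fitted()
        cells = np.atleast_1d(np.asarray(cells, dtype=float))
        return np.array(
            [core.forward_methylation(c, self.context_) for c in cells], dtype=float
        )

    def score(self, X, y) -> float:
        """Pearson correlation between predicted and true cell counts.

        Restricted to rows with status ``ok``; mirrors the calibration-curve
        statistic used to validate the assay.
        """
        from scipy.stats import pearsonr

        est = self.estimate(X)
        mask = np.array([e.ok for e in est])
        if mask.sum() < 3:
            raise InsufficientDataError("need >= 3 ok-status rows to score")
        pred = np.array([e.cells for e in est])[mask]
        return float(pearsonr(pred, np.asarray(y, dtype=float)[mask]).statistic)

    def _check_fitted(self) -> None:
        if not hasattr(self, "context_"):
            raise InsufficientDataError(
                "this SpikeInCellCounter instance is not fitted yet; call fit() first"
            )


def counter_from_context(ctx: MixtureContext) -> SpikeInCellCounter:
    """Build a fitted counter from an explicit mixture context."""
    return SpikeInCellCounter(
        copies=ctx.copies, ploidy=ctx.ploidy, a=ctx.calib.a, b=ctx.calib.b
    ).fit()
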
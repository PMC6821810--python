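"""Spike-in mixture model: copy number, forward methylation, and inversion.

The assay mixes a cell extract (genomic DNA, methylated at level ``b`` at the
target CpG) with a known mass of a non-methylated reference plasmid
(methylated at level ``a``, ideally 0).  The measured DNA-methylation
fraction of the pooled DNA then encodes the ratio of genomic alleles to
plasmid copies, from which the absolute number of cells in the extract is
recovered.

Two closed-form relations do all the work:

* copy number of the spiked reference,
  ``C_R = f * m_R * N_A / MW``  (mass in grams, molar weight in g/mol,
  ``f`` an empirical correction factor, default 1.5);
* inversion of the two-component mixture,
  ``cells = C_R * (DNAm - a) / (ploidy * (b - DNAm))``,
  the exact inverse of the copy-weighted mean
  ``DNAm = (ploidy * cells * b + C_R * a) / (ploidy * cells + C_R)``.

Everything here is scalar, pure and deterministic; vectorised estimation
lives in :mod:`spikecount.estimator`, I/O in :mod:`spikecount.io`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .exceptions import (
    InvalidContextError,
    InvalidMeasurementError,
    InvalidParameterError,
    SaturationError,
    UndefinedMixtureError,
)

#: Avogadro's constant, mol^-1 (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Default empirical prefactor of the copy-number formula.
DEFAULT_CORRECTION_FACTOR = 1.5


class EstimateStatus(str, enum.Enum):
    """Validity of a cell-count estimate.

    ``OK``            measurement fell strictly between the calibration levels.
    ``CLAMPED_BELOW`` measurement at or below the pure-plasmid level ``a``;
                      count clamped to 0.
    ``SATURATED``     measurement at or above the pure-genomic level ``b``;
                      the inversion diverges, count reported as ``inf``.
    """

    OK = "ok"
    CLAMPED_BELOW = "clamped_below"
    SATURATED = "saturated"


@dataclass(frozen=True)
class SpikeInLocus:
    """A spike-in reference amplicon and the amount added per sample.

    Parameters
    ----------
    gene_name : str
        Gene symbol of the target region (e.g. ``"LSM14B"``).
    cpg_id : str
        Array-style identifier of the interrogated CpG (e.g. ``"cg06096175"``).
    mass_ug : float
        Mass of reference DNA added to the sample, in micrograms (>= 0).
    molar_weight_g_per_mol : float
        Molar weight of the reference molecule, grams per mole (> 0).
    correction_factor : float
        Dimensionless empirical multiplier applied to the ideal copy number,
        default 1.5.
    """

    gene_name: str
    cpg_id: str
    mass_ug: float
    molar_weight_g_per_mol: float
    correction_factor: float = DEFAULT_CORRECTION_FACTOR

    def __post_init__(self) -> None:
        if not self.mass_ug >= 0:
            raise InvalidParameterError(f"mass_ug must be >= 0, got {self.mass_ug}")
        if not self.molar_weight_g_per_mol > 0:
            raise InvalidParameterError(
                f"molar_weight_g_per_mol must be > 0, got {self.molar_weight_g_per_mol}"
            )
        if not self.correction_factor > 0:
            raise InvalidParameterError(
                f"correction_factor must be > 0, got {self.correction_factor}"
            )

    def with_mass(self, mass_ug: float) -> "SpikeInLocus":
        """Return a copy of this locus with a different spiked mass."""
        return SpikeInLocus(
            self.gene_name,
            self.cpg_id,
            mass_ug,
            self.molar_weight_g_per_mol,
            self.correction_factor,
        )


# Shipped default loci.  The printed molar weights of the source protocol
# carry a negative exponent (1e-6 g/mol), below one dalton and therefore
# physically impossible for any DNA molecule; they are stored here with the
# exponent corrected to +6 (megadalton-scale amplicon/plasmid units).
LSM14B = SpikeInLocus("LSM14B", "cg06096175", mass_ug=0.022, molar_weight_g_per_mol=2.85e6)
ZC3H3 = SpikeInLocus("ZC3H3", "cg25834632", mass_ug=0.011, molar_weight_g_per_mol=2.88e6)

DEFAULT_LOCI: dict[str, SpikeInLocus] = {"LSM14B": LSM14B, "ZC3H3": ZC3H3}


class CalibrationSource(str, enum.Enum):
    DEFAULT = "default"
    FITTED = "fitted"


@dataclass(frozen=True)
class CalibrationParams:
    """Pure-component methylation levels of the two mixture end members.

    ``a`` is the methylation fraction of the pure (non-methylated) reference
    plasmid, ``b`` that of pure genomic DNA at the same CpG.  Strict
    separation ``0 <= a < b <= 1`` is required; the ideal defaults are
    ``a = 0``, ``b = 1``.
    """

    a: float = 0.0
    b: float = 1.0
    source: CalibrationSource = CalibrationSource.DEFAULT

    def __post_init__(self) -> None:
        from .exceptions import CalibrationSeparationError

        if not (0.0 <= self.a < 1.0):
            raise InvalidParameterError(f"a must lie in [0, 1), got {self.a}")
        if not (0.0 < self.b <= 1.0):
            raise InvalidParameterError(f"b must lie in (0, 1], got {self.b}")
        if not self.a < self.b:
            raise CalibrationSeparationError(
                f"pure-plasmid level a={self.a} must lie strictly below "
                f"pure-genomic level b={self.b}"
            )


@dataclass(frozen=True)
class MixtureContext:
    """Everything needed to map between cell numbers and methylation.

    Parameters
    ----------
    copies : float
        Reference copy count ``C_R`` spiked into the sample (>= 0).
    calib : CalibrationParams
        Pure-component methylation levels ``a`` (plasmid) and ``b`` (genomic).
    ploidy : int
        Genomic target alleles per cell; 2 for diploid cells (default).
    """

    copies: float
    calib: CalibrationParams = field(default_factory=CalibrationParams)
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not self.copies >= 0:
            raise InvalidParameterError(f"copies must be >= 0, got {self.copies}")
        if not (float(self.ploidy).is_integer() and self.ploidy >= 1):
            raise InvalidParameterError(f"ploidy must be a positive integer, got {self.ploidy}")


@dataclass(frozen=True)
class CellEstimate:
    """A cell-count estimate with its validity status.

    ``cells`` is finite and >= 0 for ``OK`` and ``CLAMPED_BELOW`` rows and
    ``math.inf`` (unbounded) for ``SATURATED`` rows, where the measured
    methylation reached or exceeded the pure-genomic level ``b``.
    """

    cells: float
    status: EstimateStatus
    input_dnam: float

    @property
    def ok(self) -> bool:
        return self.status is EstimateStatus.OK


def reference_copy_number(locus: SpikeInLocus) -> float:
    """Copy number of the spiked reference molecule.

    ``C_R = correction_factor * (mass_in_grams * N_A) / MW`` with the mass
    converted from micrograms to grams.  Returns 0 exactly when no mass was
    added.

    Examples
    --------
    >>> round(reference_copy_number(LSM14B) / 1e9, 2)
    6.97
    """
    mass_g = locus.mass_ug * 1e-6
    return locus.correction_factor * mass_g * AVOGADRO / locus.molar_weight_g_per_mol


def forward_methylation(cells: float, ctx: MixtureContext) -> float:
    """Expected methylation fraction of a genomic/plasmid DNA mixture.

    The pooled DNA contains ``ploidy * cells`` genomic alleles at level ``b``
    and ``copies`` plasmid molecules at level ``a``; the measured methylation
    is their copy-weighted mean.  Strictly increasing in ``cells``, equal to
    ``a`` at zero cells, tending to ``b`` as cells dominate.
    """
    if not cells >= 0:
        raise InvalidParameterError(f"cells must be >= 0, got {cells}")
    alleles = ctx.ploidy * cells
    total = alleles + ctx.copies
    if total == 0:
        raise UndefinedMixtureError("mixture with zero cells and zero reference copies")
    return (alleles * ctx.calib.b + ctx.copies * ctx.calib.a) / total


def estimate_cells(dnam: float, ctx: MixtureContext) -> CellEstimate:
    """Invert a methylation measurement to an absolute cell count.

    For ``a < dnam < b`` returns
    ``cells = copies * (dnam - a) / (ploidy * (b - dnam))`` with status
    ``OK``.  Measurements at or below ``a`` clamp to zero cells
    (``CLAMPED_BELOW``); measurements at or above ``b`` are flagged
    ``SATURATED`` with an unbounded (``inf``) count, because the genomic
    component has swamped the spike-in and the ratio is no longer
    identifiable.
    """
    if not (0.0 <= dnam <= 1.0) or math.isnan(dnam):
        raise InvalidMeasurementError(f"dnam must lie in [0, 1], got {dnam}")
    if ctx.copies == 0:
        raise InvalidContextError("cannot invert a mixture with zero reference copies")
    a, b = ctx.calib.a, ctx.calib.b
    if dnam <= a:
        return CellEstimate(0.0, EstimateStatus.CLAMPED_BELOW, dnam)
    if dnam >= b:
        return CellEstimate(math.inf, EstimateStatus.SATURATED, dnam)
    cells = ctx.copies * (dnam - a) / (ctx.ploidy * (b - dnam))
    return CellEstimate(cells, EstimateStatus.OK, dnam)


def cells_per_volume(est: CellEstimate, elution_volume_ul: float) -> float:
    """Convert a total-cell estimate to a density in cells per microliter.

    The inversion yields the total number of cells in the assayed extract;
    dividing by the elution volume of the DNA preparation expresses it per
    microliter, the unit the assay protocol reports.
    """
    if est.status is EstimateStatus.SATURATED or not math.isfinite(est.cells):
        raise SaturationError("cannot convert a saturated/unbounded estimate to a density")
    if not elution_volume_ul > 0:
        raise InvalidParameterError(
            f"elution_volume_ul must be > 0, got {elution_volume_ul}"
        )
    return est.cells / elution_volume_ul
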
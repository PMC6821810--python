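"""Synthetic pyrosequencing data for genomic/plasmid spike-in mixtures.

The generator emulates the measurement chain of the cell-counting assay:

1. the spiked reference mass is perturbed by a lognormal pipetting error
   (coefficient of variation ``mass_cv``);
2. the true mixture methylation follows the forward two-component model;
3. bisulfite artefacts shift the per-molecule methylation probability,
   ``p' = p * (1 - inappropriate_conversion_rate)
        + (1 - p) * conversion_failure_rate``;
4. a finite number of molecules (``read_depth``) is sampled — binomially,
   or beta-binomially with intra-class correlation ``rho`` to model
   overdispersion — and the reported DNAm is the methylated fraction.

All noise defaults to zero, so the default generator is the exact forward
model observed at finite depth; ``read_depth=None`` selects the exact
(infinite-depth) limit.  Every function is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import CalibrationParams, MixtureContext, SpikeInLocus
from .exceptions import InvalidDesignError

_DEFAULT_CALIB = CalibrationParams(0.02, 0.98, core.CalibrationSource.FITTED)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of a simulated pyrosequencing measurement.

    Parameters
    ----------
    read_depth : int or None
        Number of sequenced molecules per measurement; ``None`` means the
        exact infinite-depth limit (no sampling noise).
    overdispersion_rho : float
        Beta-binomial intra-class correlation in [0, 1); 0 reduces to pure
        binomial sampling.
    conversion_failure_rate : float
        Probability that an unmethylated cytosine escapes bisulfite
        conversion and reads as methylated, in [0, 0.1].
    inappropriate_conversion_rate : float
        Probability that a methylated cytosine is converted and reads as
        unmethylated, in [0, 0.1].
    mass_cv : float
        Coefficient of variation of the pipetted spike-in mass (>= 0);
        realised as a mean-one lognormal factor so masses stay positive.
    """

    read_depth: Optional[int] = 100
    overdispersion_rho: float = 0.0
    conversion_failure_rate: float = 0.0
    inappropriate_conversion_rate: float = 0.0
    mass_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.read_depth is not None and not self.read_depth >= 1:
            raise InvalidDesignError(f"read_depth must be >= 1 or None, got {self.read_depth}")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise InvalidDesignError(f"overdispersion_rho must lie in [0, 1), got {self.overdispersion_rho}")
        for name in ("conversion_failure_rate", "inappropriate_conversion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.1):
                raise InvalidDesignError(f"{name} must lie in [0, 0.1], got {v}")
        if not self.mass_cv >= 0:
            raise InvalidDesignError(f"mass_cv must be >= 0, got {self.mass_cv}")


#: Noiseless exact-readout model (infinite depth, no errors).
EXACT = NoiseModel(read_depth=None)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def _sample_methylated_fraction(
    rng: np.random.Generator, p: float, depth: Optional[int], rho: float
) -> tuple[float, Optional[int]]:
    """Draw the reported DNAm fraction at the given depth."""
    if depth is None:
        return p, None
    if rho > 0 and 0.0 < p < 1.0:
        # beta-binomial: mixing proportion ~ Beta(p*nu, (1-p)*nu), nu = 1/rho - 1
        nu = 1.0 / rho - 1.0
        p = float(rng.beta(p * nu, (1.0 - p) * nu))
    k = int(rng.binomial(depth, p))
    return k / depth, depth


def simulate_measurement(
    true_cells: float,
    locus: SpikeInLocus,
    calib: CalibrationParams,
    ploidy: int = 2,
    noise: NoiseModel = EXACT,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sim",
) -> dict:
    """Simulate one pyrosequencing readout of a spiked cell extract.

    Returns a measurement record (dict) with the observed ``dnam`` and
    ``depth`` plus truth columns ``true_cells`` and ``true_mass_ug``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mass = locus.mass_ug * _lognormal_factor(rng, noise.mass_cv)
    copies = core.reference_copy_number(locus.with_mass(mass))
    ctx = MixtureContext(copies, calib, ploidy)
    p = core.forward_methylation(true_cells, ctx)
    p_obs = (
        p * (1.0 - noise.inappropriate_conversion_rate)
        + (1.0 - p) * noise.conversion_failure_rate
    )
    dnam, depth = _sample_methylated_fraction(
        rng, p_obs, noise.read_depth, noise.overdispersion_rho
    )
    return {
        "sample_id": sample_id,
        "locus": locus.gene_name,
        "dnam": dnam,
        "depth": depth,
        "true_cells": true_cells,
        "true_mass_ug": mass,
    }


@dataclass(frozen=True)
class MixingDesign:
    """A spike-in dilution/mixing series: known cell numbers, one spike amount.

    ``true_cell_numbers`` must be strictly increasing; each point is
    measured ``replicates_per_point`` times (3 by default, the usual
    biological-replicate convention).
    """

    true_cell_numbers: Sequence[float]
    locus: SpikeInLocus
    calib: CalibrationParams = field(default_factory=CalibrationParams)
    ploidy: int = 2
    noise: NoiseModel = EXACT
    replicates_per_point: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        cells = list(self.true_cell_numbers)
        if not cells:
            raise InvalidDesignError("true_cell_numbers must be non-empty")
        if any(c < 0 for c in cells):
            raise InvalidDesignError("true_cell_numbers must be >= 0")
        if any(b <= a for a, b in zip(cells, cells[1:])):
            raise InvalidDesignError("true_cell_numbers must be strictly increasing")
        if not self.replicates_per_point >= 1:
            raise InvalidDesignError("replicates_per_point must be >= 1")


def simulate_mixing_series(design: MixingDesign) -> pd.DataFrame:
    """Simulate a full mixing series; one row per (cell number, replicate)."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for i, cells in enumerate(design.true_cell_numbers):
        for rep in range(design.replicates_per_point):
            rec = simulate_measurement(
                cells,
                design.locus,
                design.calib,
                design.ploidy,
                design.noise,
                seed=rng,
                sample_id=f"mix{i:02d}_rep{rep + 1}",
            )
            rec["replicate"] = rep + 1
            rows.append(rec)
    return pd.DataFrame(rows)


def mixing_design_for_dnam_range(
    locus: SpikeInLocus,
    n_points: int = 8,
    dnam_lo: float = 0.1,
    dnam_hi: float = 0.4,
    calib: CalibrationParams = _DEFAULT_CALIB,
    ploidy: int = 2,
    noise: NoiseModel = NoiseModel(read_depth=100),
    replicates_per_point: int = 3,
    seed: int = 0,
) -> MixingDesign:
    """Design helper: geometric cell numbers spanning a target DNAm window.

    With realistic spike amounts the reference outnumbers genomic alleles by
    orders of magnitude and the expected DNAm sits at ``a``; this helper
    inverts the forward model at ``dnam_lo`` and ``dnam_hi`` and places
    ``n_points`` geometrically spaced cell numbers between them, keeping
    the series in the informative near-linear window.
    """
    copies = core.reference_copy_number(locus)
    ctx = MixtureContext(copies, calib, ploidy)
    lo = core.estimate_cells(dnam_lo, ctx)
    hi = core.estimate_cells(dnam_hi, ctx)
    if not (lo.ok and hi.ok):
        raise InvalidDesignError("dnam_lo and dnam_hi must lie strictly between a and b")
    cells = np.geomspace(lo.cells, hi.cells, n_points)
    return MixingDesign(
        tuple(float(c) for c in cells),
        locus,
        calib,
        ploidy,
        noise,
        replicates_per_point,
        seed,
    )


def copies_for_cell_range(
    c_min: float, c_max: float, ploidy: int = 2
) -> float:
    """Spike copy number centring a cell range in the mixture's dynamic window.

    Choosing ``C_R = ploidy * sqrt(c_min * c_max)`` puts the geometric
    midpoint of the design at allele:copy odds of one, i.e. expected DNAm of
    ``(a + b) / 2`` — the most informative operating point.
    """
    if not (c_min > 0 and c_max >= c_min):
        raise InvalidDesignError("need 0 < c_min <= c_max")
    return float(ploidy * math.sqrt(c_min * c_max))


@dataclass(frozen=True)
class GrowthDesign:
    """A simulated proliferation time course mirroring the assay's use case.

    Three independent cell lines are grown under each condition and sampled
    on the listed days; true cell numbers follow
    ``initial_cells * exp(rate * day)`` with a per-line lognormal jitter on
    the rate (``rate_cv``).  Default growth rates correspond to doubling
    times of 3.5 d (plastic), 4 d (on-gel) and 5.5 d (in-gel).

    ``copies=None`` auto-selects the spike copy number with
    :func:`copies_for_cell_range` so the expected DNAm trajectory stays in
    the identifiable window for the fastest condition.
    """

    conditions: Sequence[str] = ("TCP", "on-gel", "in-gel")
    lines: Sequence[str] = ("line1", "line2", "line3")
    sampling_days: Sequence[int] = (0, 7, 14, 21)
    growth_rates: Optional[dict] = None
    initial_cells: float = 5e4
    rate_cv: float = 0.05
    copies: Optional[float] = None
    calib: CalibrationParams = _DEFAULT_CALIB
    ploidy: int = 2
    noise: NoiseModel = NoiseModel(read_depth=200)
    seed: int = 0

    def __post_init__(self) -> None:
        days = list(self.sampling_days)
        if any(d < 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidDesignError("sampling_days must be non-negative and strictly increasing")
        if not self.initial_cells > 0:
            raise InvalidDesignError("initial_cells must be > 0")
        if not self.conditions or not self.lines:
            raise InvalidDesignError("conditions and lines must be non-empty")

    def rates(self) -> dict:
        if self.growth_rates is not None:
            return dict(self.growth_rates)
        defaults = {
            "TCP": math.log(2) / 3.5,
            "on-gel": math.log(2) / 4.0,
            "in-gel": math.log(2) / 5.5,
        }
        return {c: defaults.get(c, math.log(2) / 3.5) for c in self.conditions}

    def effective_copies(self) -> float:
        if self.copies is not None:
            return float(self.copies)
        max_rate = max(self.rates().values())
        c_max = self.initial_cells * math.exp(max_rate * max(self.sampling_days))
        return copies_for_cell_range(self.initial_cells, c_max, self.ploidy)


def simulate_growth_experiment(design: GrowthDesign) -> pd.DataFrame:
    """Simulate the full time-course measurement table.

    One row per (condition, line, day) with observed ``dnam``/``depth`` and
    truth columns ``true_cells`` and ``true_rate`` (the line's jittered
    exponential growth rate, per day).
    """
    rng = np.random.default_rng(design.seed)
    copies = design.effective_copies()
    # synthetic locus carrying the requested copy number (unit mass/MW bookkeeping)
    locus = SpikeInLocus(
        "SIM", "cg_sim", mass_ug=1.0, molar_weight_g_per_mol=core.AVOGADRO * 1e-6 / copies,
        correction_factor=1.0,
    )
    rates = design.rates()
    rows = []
    for condition in design.conditions:
        for line in design.lines:
            rate = rates[condition] * _lognormal_factor(rng, design.rate_cv)
            for day in design.sampling_days:
                true_cells = design.initial_cells * math.exp(rate * day)
                rec = simulate_measurement(
                    true_cells,
                    locus,
                    design.calib,
                    design.ploidy,
                    design.noise,
                    seed=rng,
                    sample_id=f"{condition}_{line}_d{day:02d}",
                )
                rec.update(condition=condition, line=line, day=day, true_rate=rate)
                rows.append(rec)
    return pd.DataFrame(rows)
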
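"""Tables, configuration and reproducibility plumbing.

Measurement and estimate tables are delimited text (TSV canonical, CSV
accepted on read) with optional ``#``-prefixed metadata header lines that
record the package version, seed and configuration hash of the run that
produced them.  Run configuration is YAML; reports are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core
from .core import CalibrationParams, CalibrationSource, MixtureContext, SpikeInLocus
from .estimator import SpikeInCellCounter
from .exceptions import ConfigError, InvalidMeasurementError
from .simulate import NoiseModel

REQUIRED_COLUMNS = ("sample_id", "locus", "dnam")
OPTIONAL_COLUMNS = ("depth", "day", "condition", "line", "true_cells", "true_mass_ug")


def read_measurements(path, percent: bool = False) -> pd.DataFrame:
    """Read a measurement table (TSV or CSV), validating the dnam column.

    Parameters
    ----------
    path : str or Path
        Delimited-text file with at least ``sample_id``, ``locus`` and
        ``dnam`` columns; ``#`` lines are metadata and skipped.
    percent : bool
        Interpret the ``dnam`` column as percentages and divide by 100.

    Raises row-addressed errors (file row numbers, counting the header and
    any metadata lines) for unparseable or out-of-range methylation values.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_meta += 1
            else:
                break
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidMeasurementError(f"{path.name}: missing required columns {missing}")

    dnam = pd.to_numeric(df["dnam"], errors="coerce")
    # +2: 1-based file rows, one header line (plus any leading metadata lines)
    row_offset = n_meta + 2
    bad = np.flatnonzero(dnam.isna().to_numpy())
    if bad.size:
        raise InvalidMeasurementError(
            f"{path.name}, row {bad[0] + row_offset}: unparseable dnam value "
            f"{df['dnam'].iloc[bad[0]]!r}"
        )
    if percent:
        dnam = dnam / 100.0
    out_of_range = np.flatnonzero(((dnam < 0) | (dnam > 1)).to_numpy())
    if out_of_range.size:
        i = out_of_range[0]
        raise InvalidMeasurementError(
            f"{path.name}, row {i + row_offset}: dnam={df['dnam'].iloc[i]} outside "
            f"[0, 1]{'' if percent else ' (did you mean --percent?)'}"
        )
    df = df.copy()
    df["dnam"] = dnam
    return df


def write_table(df: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a TSV table with ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class RunConfig:
    """A full run configuration: loci, calibration, ploidy, noise, seed.

    Exactly one calibration source: explicit ``a``/``b`` levels, or paths to
    pure-control measurement tables (``plasmid_controls`` /
    ``genomic_controls``) from which they are fitted.
    """

    loci: dict = field(default_factory=lambda: dict(core.DEFAULT_LOCI))
    a: Optional[float] = None
    b: Optional[float] = None
    plasmid_controls: Optional[str] = None
    genomic_controls: Optional[str] = None
    ploidy: int = 2
    elution_volume_ul: Optional[float] = None
    noise: NoiseModel = NoiseModel()
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        explicit = self.a is not None or self.b is not None
        from_files = self.plasmid_controls is not None or self.genomic_controls is not None
        if explicit and from_files:
            raise ConfigError("give either explicit a/b or control-table paths, not both")
        if from_files and (self.plasmid_controls is None or self.genomic_controls is None):
            raise ConfigError("both plasmid_controls and genomic_controls paths are required")

    def calibration(self) -> CalibrationParams:
        if self.plasmid_controls is not None:
            from .calibration import fit_calibration

            plasmid = read_measurements(self.plasmid_controls)["dnam"]
            genomic = read_measurements(self.genomic_controls)["dnam"]
            return fit_calibration(plasmid, genomic)
        if self.a is None and self.b is None:
            return CalibrationParams()
        return CalibrationParams(
            self.a if self.a is not None else 0.0,
            self.b if self.b is not None else 1.0,
            CalibrationSource.FITTED,
        )

    def context_for(self, locus_name: str) -> MixtureContext:
        if locus_name not in self.loci:
            raise ConfigError(
                f"unknown locus {locus_name!r}; configured loci: {sorted(self.loci)}"
            )
        copies = core.reference_copy_number(self.loci[locus_name])
        return MixtureContext(copies, self.calibration(), self.ploidy)

    def to_dict(self) -> dict:
        return {
            "loci": {
                name: {
                    "gene_name": l.gene_name,
                    "cpg_id": l.cpg_id,
                    "mass_ug": l.mass_ug,
                    "molar_weight_g_per_mol": l.molar_weight_g_per_mol,
                    "correction_factor": l.correction_factor,
                }
                for name, l in self.loci.items()
            },
            "a": self.a,
            "b": self.b,
            "plasmid_controls": self.plasmid_controls,
            "genomic_controls": self.genomic_controls,
            "ploidy": self.ploidy,
            "elution_volume_ul": self.elution_volume_ul,
            "noise": {
                "read_depth": self.noise.read_depth,
                "overdispersion_rho": self.noise.overdispersion_rho,
                "conversion_failure_rate": self.noise.conversion_failure_rate,
                "inappropriate_conversion_rate": self.noise.inappropriate_conversion_rate,
                "mass_cv": self.noise.mass_cv,
            },
            "seed": self.seed,
        }

    def hash(self) -> str:
        """Short stable hash of the canonicalised configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    loci = {}
    for entry in raw.get("loci", []):
        try:
            locus = SpikeInLocus(
                gene_name=entry["gene_name"],
                cpg_id=entry.get("cpg_id", ""),
                mass_ug=float(entry["mass_ug"]),
                molar_weight_g_per_mol=float(entry["molar_weight_g_per_mol"]),
                correction_factor=float(
                    entry.get("correction_factor", core.DEFAULT_CORRECTION_FACTOR)
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"locus entry missing field {exc}") from exc
        loci[locus.gene_name] = locus
    calib = raw.get("calibration", {}) or {}
    noise_raw = raw.get("noise", {}) or {}
    try:
        noise = NoiseModel(**noise_raw)
    except TypeError as exc:
        raise ConfigError(f"bad noise model: {exc}") from exc
    return RunConfig(
        loci=loci or dict(core.DEFAULT_LOCI),
        a=calib.get("a"),
        b=calib.get("b"),
        plasmid_controls=calib.get("plasmid_controls"),
        genomic_controls=calib.get("genomic_controls"),
        ploidy=int(raw.get("ploidy", 2)),
        elution_volume_ul=raw.get("elution_volume_ul"),
        noise=noise,
        seed=raw.get("seed"),
    )


def run_count(config: RunConfig, measurements: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell counts for every row of a measurement table.

    Adds ``copies``, ``cells``, ``status`` and (when an elution volume is
    configured) ``cells_per_ul`` columns.  Deterministic: no randomness is
    involved in counting.
    """
    calib = config.calibration()
    counters: dict[str, SpikeInCellCounter] = {}
    for name, locus in config.loci.items():
        counters[name] = SpikeInCellCounter(
            locus=locus, ploidy=config.ploidy, a=calib.a, b=calib.b
        ).fit()

    out = measurements.copy()
    copies_col, cells_col, status_col, density_col = [], [], [], []
    for _, row in out.iterrows():
        name = row["locus"]
        if name not in counters:
            raise ConfigError(
                f"unknown locus {name!r} in measurements; configured: {sorted(counters)}"
            )
        counter = counters[name]
        est = counter.estimate([row["dnam"]])[0]
        copies_col.append(counter.copies_)
        cells_col.append(est.cells)
        status_col.append(est.status.value)
        if config.elution_volume_ul is not None:
            density_col.append(
                est.cells / config.elution_volume_ul if est.ok else np.nan
            )
    out["copies"] = copies_col
    out["cells"] = cells_col
    out["status"] = status_col
    if config.elution_volume_ul is not None:
        out["cells_per_ul"] = density_col
    return out


def locus_mean_estimates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-locus cell estimates per sample.

    When a sample was measured at several spike-in loci the per-locus
    estimates are averaged (status-ok rows only); a single-locus sample
    passes through unchanged.  This combination rule is a package choice —
    no weighting scheme across loci is established for this assay.
    """
    ok = estimates[estimates["status"] == "ok"]
    if ok.empty:
        return ok.copy()
    keys = [c for c in ("sample_id", "condition", "line", "day") if c in ok.columns]
    return ok.groupby(keys, dropna=False, as_index=False).agg(
        cells=("cells", "mean"), n_loci=("locus", "nunique")
    )
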
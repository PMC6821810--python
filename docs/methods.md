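# Methods

## The measurement model

A sample containing an unknown number of cells is mixed with a known mass
`m_R` of a reference plasmid carrying the non-methylated sequence of a
target region, then the DNA is isolated and bisulfite-pyrosequenced at one
CpG site. The model makes three assumptions:

1. the target CpG is (near-)fully methylated in genomic DNA and
   (near-)non-methylated on the plasmid — quantified by the calibration
   levels `b` and `a`;
2. every cell contributes exactly `ploidy` target alleles (2 for diploid
   cells; aneuploid or replicating populations violate this
   proportionally);
3. plasmid and genomic molecules are amplified and sequenced with equal
   efficiency, up to the constant correction factor `f` absorbed into the
   copy number.

Under these assumptions the measured methylation fraction is the
copy-weighted mean of the two pure levels,

    DNAm = (ploidy·cells·b + C_R·a) / (ploidy·cells + C_R),

which is strictly increasing in `cells`, equals `a` at zero cells and
saturates at `b`. Its exact inverse,

    cells = C_R · (DNAm − a) / (ploidy · (b − DNAm)),

is the estimator. `C_R = f·m_R·N_A/MW` with `N_A = 6.02214076 × 10²³
mol⁻¹`.

### Units of the shipped molar weights

The assay protocol this package ships defaults for quotes molar weights of
`2.85 × 10⁻⁶ g mol⁻¹` (LSM14B reference) and `2.88 × 10⁻⁶ g mol⁻¹`
(ZC3H3). A molar weight below one dalton is physically impossible for any
molecule; a plasmid-scale DNA molecule weighs megadaltons. The exponents
are therefore read as typeset errors for `10⁶`, and the package stores
2.85 × 10⁶ and 2.88 × 10⁶ g/mol. With the shipped masses (0.022 µg and
0.011 µg) this yields C_R ≈ 6.97 × 10⁹ and ≈ 3.45 × 10⁹ copies
respectively.

### The correction factor

The 1.5 prefactor of the copy-number formula is an empirical constant of
the source protocol without a stated derivation. It is exposed as a
configurable `correction_factor` per locus, defaulting to 1.5 so the
shipped behaviour matches the protocol as printed.

### Totals versus densities

`C_R` is a total copy count, so the inversion returns the **total** number
of cells represented in the assayed extract. Expressing it "per µl"
requires the elution volume of the DNA preparation; `cells_per_volume` (and
the `elution_volume_ul` config key) make that division explicit rather than
folding an implicit volume into the formula.

### Degenerate inputs

- DNAm ≤ a: clamped to 0 cells, status `clamped_below` (a negative count
  would be an artefact of calibration error).
- DNAm ≥ b: status `saturated`, count `inf` — the spike-in is exhausted and
  the ratio is unidentifiable. `inf` (not a string sentinel) keeps count
  columns numeric; downstream stages exclude non-`ok` rows and count them.
- A mixture with zero cells and zero copies has no defined methylation and
  raises.
- Calibration requires strict separation `0 ≤ a < b ≤ 1`; construction
  fails otherwise (swapped controls).

Two loci measured on the same sample give two estimates; the package
reports both and offers an unweighted mean (`locus_mean_estimates`). No
principled weighting between loci is established for this assay, so none is
defaulted.

## Calibration

`a` and `b` are arithmetic means of pure-plasmid and pure-genomic control
measurements (unweighted by default; read-depth weighting available).
Defaults when no controls are provided are the ideal `a = 0`, `b = 1`.
Whether calibration levels are locus-specific is left to the user; the
estimator attaches one calibration per counter, so per-locus calibration is
the natural usage.

## Synthetic data generator

The simulator emulates the measurement chain so every downstream stage is
testable without experimental data:

- **pipetting error** on the spiked mass: mean-one lognormal factor with
  coefficient of variation `mass_cv` (lognormal keeps masses positive);
- **bisulfite artefacts**: conversion failures (unmethylated reads
  methylated, rate `conversion_failure_rate`) and inappropriate conversion
  (the reverse, `inappropriate_conversion_rate`) shift the per-molecule
  probability linearly;
- **finite read depth**: the reported DNAm is a binomial fraction at
  `read_depth` molecules, or beta-binomial with intra-class correlation
  `overdispersion_rho` (mixing proportion Beta(p·ν, (1−p)·ν), ν = 1/ρ − 1)
  to model run-to-run overdispersion. `read_depth=None` is the exact
  infinite-depth limit.

All noise defaults to zero. Defaults chosen for the shipped designs, with
units:

| parameter | default | why |
|---|---|---|
| mixing series points | 8, geometric | spans the near-linear window below saturation |
| replicates per point | 3 | the standard biological-replicate convention |
| read depth (mixing) | 100 molecules | conservative pyrosequencing depth |
| expected DNAm window | 0.1–0.4 | informative, far from both clamp and saturation |
| growth rates | ln2/3.5, ln2/4, ln2/5.5 d⁻¹ | doubling 3.5–5.5 d, realistic for proliferating iPSC-derived cells across substrate conditions |
| initial cells | 5 × 10⁴ | multiwell-plate scale seeding |
| per-line rate jitter CV | 5% | line-to-line biological variability |
| sampling days | 0, 7, 14, 21 | weekly sampling over a three-week differentiation |
| read depth (growth) | 200 molecules | longer assay runs at higher depth |

**Operating regime.** With the real spike amounts (C_R ≈ 7 × 10⁹) and
realistic cell numbers (≤ 10⁶) the expected DNAm sits at `a` and carries no
information. The simulator therefore exposes the copy number directly and
provides two design helpers: `mixing_design_for_dnam_range` inverts the
forward model at a target DNAm window, and `copies_for_cell_range` picks
`C_R = ploidy·√(c_min·c_max)`, which places the geometric midpoint of a
design at allele:copy odds of one, i.e. expected DNAm `(a+b)/2`. The
simulated mixing series consequently uses large nominal cell numbers
(~10⁸–10⁹ against the LSM14B spike); the estimator is scale-free, so only
the allele:copy ratio matters.

**What the simulator does not emulate:** pyrogram signal processing, PCR
amplification bias between plasmid and genomic templates beyond the
constant correction factor, DNA-extraction losses, and cell-cycle variation
in allele number. Passing simulation-based tests therefore demonstrates
correctness of the estimator and pipeline under the stated noise model, not
robustness to these real-data effects.

## Validation statistics

The mixing-series validator reports two Pearson correlations: measured DNAm
vs true cell number — computed on per-mixture replicate means, as a
standard curve is read — and inverted estimates vs truth (the relation that
is linear whenever the model holds; DNAm vs cells is concave outside the
low-fraction regime). Correlations are raw-scale by default with a log10
option. Per-measurement relative errors are reported for status-`ok` rows;
clamped/saturated rows are counted and excluded.

At read depth 100 the binomial noise floor is σ ≈ 0.03–0.05 per
measurement, so the standard-curve correlation of an 8-point series
spanning DNAm 0.1–0.4 fluctuates around ≈ 0.975 (seed-dependent by a few
hundredths); it approaches 1 as depth grows. Real pyrosequencing averages
over ~10⁵ molecules, so measured series can correlate more tightly than
this conservative simulation.

## Growth curves

Estimates are grouped per condition, aligned on sampling days across
replicate lines, and summarised as mean ± sample SD (n−1) across lines —
SD is defined only where ≥ 2 lines contribute; days covered by a subset of
lines are retained and flagged (`partial_days`). Doubling time is
`ln 2 / slope` from an OLS fit of ln(cells) on day, computed per line or on
the cross-line mean curve (the default and the package's headline summary);
a non-positive slope returns the `NON_GROWING` sentinel (`inf`). Two points
reduce OLS to the exact closed form. Chamber-count cross-validation matches
estimates to hemocytometer counts on (condition, line, day), reports
estimated/chamber ratios and, with ≥ 3 pairs, a Pearson correlation;
"similar range" is operationalised as all ratios within a configurable
band, default [1/3, 3].

## Numerical notes

- The inversion is the algebraically exact inverse of the forward model;
  round trips are accurate to ≲ 10⁻⁹ relative error over the practical
  parameter range. Near the boundaries the subtraction `DNAm − a` (or
  `b − DNAm`) cancels catastrophically, leaving an absolute error floor of
  order `C_R · ε` (ε machine precision); the property tests encode this
  floor explicitly.
- DNAm is a fraction in [0, 1] everywhere inside the package; percent
  input is converted once at the I/O boundary (`--percent`).
- All randomness flows through a single `numpy.random.Generator` seeded per
  design, so identical designs and seeds give bit-identical tables.
- Output tables carry `#`-prefixed metadata headers (package version, seed,
  configuration hash) for provenance.

## Problem sizes

The shipped test and validation designs use 8–9 mixture points × 3
replicates, 10⁴-draw moment checks, and a 3 × 3 × 4 growth table — sizes at
which every statistical check is stable while the full suite runs in
seconds.
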
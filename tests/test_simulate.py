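"""Synthetic pyrosequencing generator: noise model, determinism, designs."""

import math

import numpy as np
import pandas as pd
import pytest

from spikecount import (
    EXACT,
    CalibrationParams,
    GrowthDesign,
    MixingDesign,
    MixtureContext,
    NoiseModel,
    copies_for_cell_range,
    forward_methylation,
    mixing_design_for_dnam_range,
    simulate_growth_experiment,
    simulate_measurement,
    simulate_mixing_series,
)
from spikecount.core import LSM14B
from spikecount.exceptions import InvalidDesignError


class TestSimulateMeasurement:
    def test_exact_mode_reproduces_forward_model(self, unit_locus, wide_calib):
        ctx = MixtureContext(1e6, wide_calib)
        expected = forward_methylation(1e5, ctx)
        rec = simulate_measurement(1e5, unit_locus, wide_calib, noise=EXACT, seed=7)
        assert rec["dnam"] == expected
        assert rec["depth"] is None

    def test_zero_cells_ideal_plasmid_reads_zero(self, unit_locus):
        calib = CalibrationParams(0.0, 1.0)
        rec = simulate_measurement(
            0.0, unit_locus, calib, noise=NoiseModel(read_depth=50), seed=3
        )
        assert rec["dnam"] == 0.0

    def test_binomial_moments_at_half(self, unit_locus):
        """Mean and SD of the readout match binomial theory at p=0.5."""
        calib = CalibrationParams(0.0, 1.0)
        noise = NoiseModel(read_depth=100)
        rng = np.random.default_rng(42)
        # 2*cells = copies -> p = 0.5 exactly
        draws = np.array(
            [
                simulate_measurement(5e5, unit_locus, calib, 2, noise, seed=rng)["dnam"]
                for _ in range(10_000)
            ]
        )
        se = 0.05 / math.sqrt(10_000)
        assert abs(draws.mean() - 0.5) < 3 * se
        assert abs(draws.std(ddof=1) - 0.05) < 0.1 * 0.05

    def test_law_of_large_numbers_at_high_depth(self, unit_locus, wide_calib):
        ctx = MixtureContext(1e6, wide_calib)
        p = forward_methylation(3e5, ctx)
        noise = NoiseModel(read_depth=1_000_000)
        rec = simulate_measurement(3e5, unit_locus, wide_calib, noise=noise, seed=11)
        assert abs(rec["dnam"] - p) < 3e-3

    def test_overdispersion_inflates_variance(self, unit_locus):
        """Beta-binomial draws spread wider than binomial at equal depth."""
        calib = CalibrationParams(0.0, 1.0)
        rng_b = np.random.default_rng(5)
        rng_bb = np.random.default_rng(5)
        kw = dict(ploidy=2)
        binom = np.array(
            [
                simulate_measurement(
                    5e5, unit_locus, calib, noise=NoiseModel(read_depth=100), seed=rng_b, **kw
                )["dnam"]
                for _ in range(10_000)
            ]
        )
        bbinom = np.array(
            [
                simulate_measurement(
                    5e5,
                    unit_locus,
                    calib,
                    noise=NoiseModel(read_depth=100, overdispersion_rho=0.05),
                    seed=rng_bb,
                    **kw,
                )["dnam"]
                for _ in range(10_000)
            ]
        )
        assert bbinom.var(ddof=1) > binom.var(ddof=1)

    def test_conversion_errors_shift_probability(self, unit_locus):
        calib = CalibrationParams(0.0, 1.0)
        # pure plasmid (p = 0) with 5% conversion failure reads ~0.05 exactly at inf depth
        noise = NoiseModel(read_depth=None, conversion_failure_rate=0.05)
        rec = simulate_measurement(0.0, unit_locus, calib, noise=noise, seed=1)
        assert rec["dnam"] == pytest.approx(0.05)
        # fully saturated (p -> 1) with 4% inappropriate conversion reads ~0.96
        noise = NoiseModel(read_depth=None, inappropriate_conversion_rate=0.04)
        rec = simulate_measurement(1e12, unit_locus, calib, noise=noise, seed=1)
        assert rec["dnam"] == pytest.approx(0.96, abs=1e-4)

    def test_mass_jitter_perturbs_spike_mass(self, unit_locus, wide_calib):
        noise = NoiseModel(read_depth=None, mass_cv=0.1)
        rng = np.random.default_rng(9)
        masses = np.array(
            [
                simulate_measurement(1e5, unit_locus, wide_calib, noise=noise, seed=rng)[
                    "true_mass_ug"
                ]
                for _ in range(2000)
            ]
        )
        assert np.all(masses > 0)
        assert masses.mean() == pytest.approx(unit_locus.mass_ug, rel=0.02)
        assert masses.std(ddof=1) / masses.mean() == pytest.approx(0.1, rel=0.15)

    def test_invalid_depth_rejected(self):
        with pytest.raises(InvalidDesignError):
            NoiseModel(read_depth=0)


class TestMixingSeries:
    def test_noiseless_series_is_strictly_increasing(self, noiseless_series):
        assert noiseless_series["dnam"].is_monotonic_increasing
        assert len(noiseless_series) == 6

    def test_seed_determinism(self, unit_locus, wide_calib):
        design = MixingDesign(
            (100.0, 1000.0, 10_000.0),
            unit_locus,
            wide_calib,
            noise=NoiseModel(read_depth=100, mass_cv=0.05),
            seed=77,
        )
        pd.testing.assert_frame_equal(
            simulate_mixing_series(design), simulate_mixing_series(design)
        )

    def test_different_seeds_differ(self, unit_locus, wide_calib):
        kw = dict(
            true_cell_numbers=(100.0, 1000.0, 10_000.0),
            locus=unit_locus,
            calib=wide_calib,
            noise=NoiseModel(read_depth=100),
        )
        t1 = simulate_mixing_series(MixingDesign(seed=1, **kw))
        t2 = simulate_mixing_series(MixingDesign(seed=2, **kw))
        assert not t1["dnam"].equals(t2["dnam"])

    def test_design_invariants(self, unit_locus):
        with pytest.raises(InvalidDesignError):
            MixingDesign((), unit_locus)
        with pytest.raises(InvalidDesignError):
            MixingDesign((100.0, 100.0), unit_locus)
        with pytest.raises(InvalidDesignError):
            MixingDesign((100.0, 50.0), unit_locus)

    def test_design_helper_spans_requested_window(self):
        from spikecount import reference_copy_number

        design = mixing_design_for_dnam_range(LSM14B, dnam_lo=0.1, dnam_hi=0.4, seed=0)
        ctx = MixtureContext(
            reference_copy_number(LSM14B), design.calib, design.ploidy
        )
        assert len(design.true_cell_numbers) == 8
        ratios = np.diff(np.log(design.true_cell_numbers))
        np.testing.assert_allclose(ratios, ratios[0])  # geometric spacing
        p_lo = forward_methylation(design.true_cell_numbers[0], ctx)
        p_hi = forward_methylation(design.true_cell_numbers[-1], ctx)
        assert p_lo == pytest.approx(0.1, abs=0.02)
        assert p_hi == pytest.approx(0.4, abs=0.02)


class TestGrowthExperiment:
    def test_zero_rate_zero_noise_is_constant(self, wide_calib):
        design = GrowthDesign(
            conditions=("flat",),
            growth_rates={"flat": 0.0},
            noise=EXACT,
            rate_cv=0.0,
            calib=wide_calib,
            seed=0,
        )
        table = simulate_growth_experiment(design)
        assert table["true_cells"].nunique() == 1
        assert table.groupby("line")["dnam"].nunique().eq(1).all()

    def test_doubling_rate_closed_form(self, wide_calib):
        design = GrowthDesign(
            conditions=("fast",),
            lines=("l1",),
            sampling_days=(0, 1),
            growth_rates={"fast": math.log(2)},
            noise=EXACT,
            rate_cv=0.0,
            calib=wide_calib,
            seed=0,
        )
        table = simulate_growth_experiment(design).sort_values("day")
        assert table["true_cells"].iloc[1] == pytest.approx(
            2 * table["true_cells"].iloc[0]
        )

    def test_default_design_shape_and_truth_columns(self):
        table = simulate_growth_experiment(GrowthDesign(seed=4))
        assert len(table) == 3 * 3 * 4
        assert {"condition", "line", "day", "dnam", "true_cells", "true_rate"} <= set(
            table.columns
        )
        # expected DNAm trajectory stays inside the identifiable window
        assert table["dnam"].between(0.03, 0.97).all()

    def test_seed_determinism(self):
        d = GrowthDesign(seed=123)
        pd.testing.assert_frame_equal(
            simulate_growth_experiment(d), simulate_growth_experiment(d)
        )

    def test_copies_helper_centres_midpoint(self):
        copies = copies_for_cell_range(1e3, 1e7, ploidy=2)
        ctx = MixtureContext(copies, CalibrationParams(0.0, 1.0))
        mid = math.sqrt(1e3 * 1e7)
        assert forward_methylation(mid, ctx) == pytest.approx(0.5)

    def test_invalid_days_rejected(self):
        with pytest.raises(InvalidDesignError):
            GrowthDesign(sampling_days=(0, 7, 7))
        with pytest.raises(InvalidDesignError):
            GrowthDesign(sampling_days=(-1, 7))
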
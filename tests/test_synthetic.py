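import itertools
import math

import numpy as np
import pytest
from scipy import stats

from scbc import (
    CohortCondition,
    generate_chip,
    generate_cohort,
    get_scenario,
    inject_gradient,
    load_scenario,
    save_scenario,
)
from scbc.synthetic import (
    GAUSSIAN_TAIL_2SIGMA,
    ConfigError,
    SyntheticChipConfig,
    derive_seed,
    poisson_binomial_tail,
    solve_secreting_fraction,
)


def flat_config(**kw):
    defaults = dict(occupancy={0: 300, 1: 400}, secreting_fraction=0.0)
    defaults.update(kw)
    return SyntheticChipConfig(**defaults)


COND = CohortCondition("c", 4.0, 20.0)


def chips_equal(a, b):
    return all(
        x.chamber_id == y.chamber_id
        and x.cell_count == y.cell_count
        and np.array_equal(x.raw_intensity, y.raw_intensity)
        and np.array_equal(x.saturated, y.saturated)
        for x, y in zip(a.chambers, b.chambers)
    )


class TestGenerateChip:
    def test_determinism_bitwise(self):
        cfg = flat_config(secreting_fraction=0.3, analyte_activity=0.4)
        assert chips_equal(
            generate_chip(cfg, COND, seed=11), generate_chip(cfg, COND, seed=11)
        )

    def test_explicit_occupancy_exact(self):
        cfg = SyntheticChipConfig(occupancy={0: 300, 1: 400, 2: 350, 3: 200})
        ds = generate_chip(cfg, COND, seed=0)
        counts = np.bincount(ds.cell_counts())
        assert counts.tolist() == [300, 400, 350, 200]

    def test_poisson_occupancy_matches_pmf(self):
        lam, n = 1.0, 10_000
        cfg = SyntheticChipConfig(poisson_lambda=lam, n_chambers=n)
        ds = generate_chip(cfg, COND, seed=5)
        counts = ds.cell_counts()
        kmax = 6
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = np.array(
            [stats.poisson.pmf(k, lam) for k in range(kmax)] + [stats.poisson.sf(kmax - 1, lam)]
        ) * n
        gof = stats.chisquare(observed, expected)
        assert gof.pvalue > 1e-3
        # zero-cell count near n e^-lambda, within 3 binomial s.e.
        p0 = math.exp(-lam)
        assert abs((counts == 0).sum() - n * p0) < 3 * math.sqrt(n * p0 * (1 - p0))

    def test_null_chip_exceeds_true_cutoff_at_gaussian_tail_rate(self):
        cfg = flat_config()
        ds = generate_chip(cfg, COND, seed=2)
        cutoff = 106.0 + 2 * 16.2
        singles = np.vstack([c.raw_intensity for c in ds.single_cell()])
        n = singles.shape[0]
        se = math.sqrt(GAUSSIAN_TAIL_2SIGMA * (1 - GAUSSIAN_TAIL_2SIGMA) / n)
        for j in range(singles.shape[1]):
            rate = np.mean(singles[:, j] > cutoff)
            assert abs(rate - GAUSSIAN_TAIL_2SIGMA) < 3 * se

    def test_saturation_ceiling_clips_and_flags(self):
        cfg = flat_config(
            occupancy={0: 50, 1: 50},
            secreting_fraction=1.0,
            analyte_activity=1.0,
            signal_log_mean=math.log(1e5),
        )
        ds = generate_chip(cfg, COND, seed=1)
        singles = ds.single_cell()
        assert all((c.raw_intensity <= cfg.saturation_ceiling).all() for c in singles)
        assert any(c.saturated.any() for c in singles)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticChipConfig(occupancy={0: 10}, secreting_fraction=1.5)
        with pytest.raises(ConfigError):
            SyntheticChipConfig(occupancy={0: 10}, background_sigma=0.0)
        with pytest.raises(ConfigError):
            SyntheticChipConfig(poisson_lambda=None, n_chambers=None)


class TestInjectGradient:
    def test_zero_slope_is_identity(self):
        ds = generate_chip(flat_config(), COND, seed=4)
        assert chips_equal(ds, inject_gradient(ds, 0.0))

    def test_inject_then_negate_recovers(self):
        ds = generate_chip(flat_config(), COND, seed=4)
        back = inject_gradient(inject_gradient(ds, 0.5), -0.5)
        for a, b in zip(ds.chambers, back.chambers):
            assert np.allclose(a.raw_intensity, b.raw_intensity, atol=1e-9)

    def test_input_unmodified_and_offset_arithmetic(self):
        ds = generate_chip(
            SyntheticChipConfig(occupancy={0: 1000}), COND, seed=4
        )  # 1000 chambers / 25 cols -> rows 0..39
        before = ds.intensity_matrix().copy()
        out = inject_gradient(ds, 0.5)
        assert np.array_equal(ds.intensity_matrix(), before)
        rows = ds.rows()
        delta = out.intensity_matrix() - before
        assert np.allclose(delta[rows == 39], 0.5 * 39)
        assert np.allclose(delta[rows == 0], 0.0)
        top = delta[rows == 39].mean() - delta[rows == 0].mean()
        assert abs(top - 19.5) < 1e-9


class TestCohorts:
    def test_ot1_t2_windows_from_constant_total(self):
        sc = get_scenario("OT1_tetramer")
        assert [cond.T2_hours for cond, _ in sc.conditions] == [23.8, 20.0, 8.0]

    def test_cohort_deterministic(self):
        sc = get_scenario("density_sweep")
        a = generate_cohort(sc, 9)
        b = generate_cohort(sc, 9)
        assert len(a) == len(b) == 2
        assert all(chips_equal(x, y) for x, y in zip(a, b))

    def test_single_condition_scenario(self):
        sc = get_scenario("density_sweep")
        sc.conditions = sc.conditions[:1]
        assert len(generate_cohort(sc, 0)) == 1

    def test_derived_seeds_distinct_and_bounded(self):
        seeds = [derive_seed(1, i) for i in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)
        assert seeds == [derive_seed(1, i) for i in range(10)]

    def test_scenario_yaml_round_trip(self, tmp_path):
        sc = get_scenario("human_CD8")
        path = tmp_path / "sc.yaml"
        save_scenario(sc, path)
        sc2 = load_scenario(path)
        assert sc2.name == sc.name
        assert [c.label for c, _ in sc2.conditions] == [c.label for c, _ in sc.conditions]
        assert all(
            chips_equal(x, y)
            for x, y in zip(generate_cohort(sc, 3), generate_cohort(sc2, 3))
        )


class TestCalibrationArithmetic:
    def test_poisson_binomial_tail_matches_enumeration(self):
        probs = [0.1, 0.5, 0.9, 0.3]
        for min_k in range(len(probs) + 1):
            brute = sum(
                math.prod(p if b else 1 - p for p, b in zip(probs, bits))
                for bits in itertools.product([0, 1], repeat=len(probs))
                if sum(bits) >= min_k
            )
            assert poisson_binomial_tail(probs, min_k) == pytest.approx(brute, abs=1e-12)

    def test_solved_fraction_brackets(self):
        activity = np.full(11, 0.5)
        p = solve_secreting_fraction(0.5, activity, min_k=1)
        assert 0 < p < 1
        with pytest.raises(ConfigError):
            solve_secreting_fraction(0.01, activity, min_k=1)  # below the null FP rate

    def test_solved_fraction_recovered_by_generator(self):
        """Measured >=1-call fraction lands on the calibration target (3 s.e.)."""
        target = 0.40
        activity = np.full(11, 0.5)
        p = solve_secreting_fraction(target, activity, min_k=1)
        cfg = SyntheticChipConfig(
            occupancy={0: 300, 1: 1600},
            secreting_fraction=p,
            analyte_activity=activity,
            signal_log_mean=math.log(40.0),
        )
        ds = generate_chip(cfg, COND, seed=6)
        cutoff = 106.0 + 2 * 16.2
        singles = np.vstack([c.raw_intensity for c in ds.single_cell()])
        measured = np.mean((singles > cutoff).sum(axis=1) >= 1)
        assert abs(measured - target) < 3 * math.sqrt(target * (1 - target) / 1600)
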
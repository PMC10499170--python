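import numpy as np
import pytest

from sphersim import (
    build_covariance,
    cohens_f,
    epsilon_eigen_oracle,
    epsilon_hat,
    epsilon_lower_bound,
    mean_patterns,
    sample_mvn,
    scale_pattern_to_f,
)
from sphersim.simulation_engine import EPSILON_GRIDS
from sphersim.synthetic_data import MeanPattern, _box_epsilon_of_spectrum, _geometric_spectrum


class TestBuildCovariance:
    @pytest.mark.parametrize(
        "k,target",
        [(k, t) for k, grid in EPSILON_GRIDS.items() for t in grid],
    )
    def test_hits_every_grid_target(self, k, target):
        spec = build_covariance(k, target)
        lb = epsilon_lower_bound(k)
        realized = epsilon_hat(spec.matrix)
        if target <= lb + 1e-12:
            # the bound itself is open: realized sits just above it
            assert 0 <= realized - target <= 1e-8
        else:
            assert realized == pytest.approx(target, abs=1e-8)
        # verified independently through the eigenvalue formulation
        assert epsilon_eigen_oracle(spec.matrix) == pytest.approx(target, abs=1e-7)

    def test_sphericity_target_gives_identity_spectrum(self):
        spec = build_covariance(4, 1.0)
        assert np.allclose(spec.matrix.entries, np.eye(4), atol=1e-12)

    def test_family_is_monotone_in_parameter(self):
        rs = np.linspace(0.01, 1.0, 50)
        eps = [_box_epsilon_of_spectrum(_geometric_spectrum(r, 5), 5) for r in rs]
        assert np.all(np.diff(eps) > 0)

    def test_deterministic(self):
        a = build_covariance(6, 0.4)
        b = build_covariance(6, 0.4)
        assert np.array_equal(a.matrix.entries, b.matrix.entries)

    def test_rejects_out_of_range_target(self):
        with pytest.raises(ValueError, match="outside"):
            build_covariance(4, 0.2)
        with pytest.raises(ValueError, match="outside"):
            build_covariance(4, 1.2)

    def test_off_grid_targets_near_bound(self):
        # fine targets below the geometric family's reach use the flat tail
        spec = build_covariance(6, 0.201)
        assert spec.realized_eps == pytest.approx(0.201, abs=1e-8)


class TestSampleMvn:
    def test_sample_covariance_converges_to_identity(self):
        spec = build_covariance(3, 1.0)
        block = sample_mvn(spec, np.zeros(3), 100_000, seed=1)
        S = np.cov(block.values, rowvar=False)
        assert np.abs(S - np.eye(3)).max() < 0.02

    def test_same_seed_bitwise_identical(self):
        spec = build_covariance(4, 0.7)
        a = sample_mvn(spec, np.zeros(4), 50, seed=9)
        b = sample_mvn(spec, np.zeros(4), 50, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_sample_epsilon_consistent_at_large_n(self):
        spec = build_covariance(4, 0.5)
        block = sample_mvn(spec, np.zeros(4), 200_000, seed=3)
        S = np.cov(block.values, rowvar=False)
        assert epsilon_hat(S, validate=False) == pytest.approx(0.5, abs=0.01)

    def test_sample_mean_converges(self):
        spec = build_covariance(3, 0.8)
        mean = np.array([1.0, -2.0, 0.5])
        block = sample_mvn(spec, mean, 100_000, seed=4)
        se = np.sqrt(np.diag(spec.matrix.entries) / 100_000)
        assert np.all(np.abs(block.values.mean(axis=0) - mean) < 5 * se)

    def test_rejects_tiny_n(self):
        spec = build_covariance(3, 1.0)
        with pytest.raises(ValueError):
            sample_mvn(spec, np.zeros(3), 1, seed=0)


class TestMeanPatterns:
    def test_three_patterns_per_k(self):
        for k in (3, 4, 6):
            assert len(mean_patterns(k)) == 3

    def test_k3_shapes(self):
        bases = [p.base_vector for p in mean_patterns(3)]
        assert (1.0, 1.0, 2.0) in bases
        assert (1.0, 2.0, 1.0) in bases

    def test_k4_includes_half_different_and_linear(self):
        patterns = {p.label: p for p in mean_patterns(4)}
        assert patterns["half_high"].base_vector == (1.0, 1.0, 2.0, 2.0)
        linear = np.array(patterns["linear"].base_vector)
        assert np.allclose(linear, [1.0, 1.75, 2.5, 3.25])
        assert np.allclose(np.diff(linear), np.diff(linear)[0])

    def test_k6_includes_half_different(self):
        bases = [p.base_vector for p in mean_patterns(6)]
        assert (1.0, 1.0, 1.0, 2.0, 2.0, 2.0) in bases

    def test_rejects_small_k(self):
        with pytest.raises(ValueError):
            mean_patterns(2)


class TestScalePatternToF:
    def test_closed_form_linear_identity_k3(self):
        # deviations (-d, 0, d) on identity: f = d * sqrt(2/3)
        linear = next(p for p in mean_patterns(3) if p.kind == "linear")
        scaled = scale_pattern_to_f(linear, np.eye(3), 0.25)
        d = 0.25 * np.sqrt(3 / 2)
        assert np.allclose(scaled.scaled_vector, [-d, 0.0, d], atol=1e-12)

    def test_roundtrip_f_equals_target(self):
        for k in (3, 4, 6):
            S = build_covariance(k, 0.6).matrix
            for p in mean_patterns(k):
                scaled = scale_pattern_to_f(p, S, 0.25)
                assert cohens_f(scaled.scaled_vector, S) == pytest.approx(
                    0.25, abs=1e-12
                )

    def test_linearity_in_target(self):
        p = mean_patterns(4)[0]
        S = build_covariance(4, 0.7).matrix
        v1 = np.array(scale_pattern_to_f(p, S, 0.1).scaled_vector)
        v3 = np.array(scale_pattern_to_f(p, S, 0.3).scaled_vector)
        assert np.allclose(v3, 3 * v1, atol=1e-12)

    def test_flat_pattern(self):
        flat = MeanPattern("flat", "flat", (1.0, 1.0, 1.0))
        scaled = scale_pattern_to_f(flat, np.eye(3), 0.0)
        assert scaled.scaled_vector == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="flat"):
            scale_pattern_to_f(flat, np.eye(3), 0.25)
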
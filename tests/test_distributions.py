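import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relca.distributions import (
    DispersionComponents,
    DistributionSpec,
    FittingError,
    back_calc_sigma,
    combine_components,
    fit_distribution,
    lognormal_from_mean,
    sample,
)


class TestSpecValidation:
    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("beta", 1.0, 2.0)

    @pytest.mark.parametrize(
        "kind,params",
        [
            ("lognormal", (1.0, 0.9, None)),  # gsd < 1
            ("normal", (0.0, -1.0, None)),
            ("triangular", (0.0, 2.0, 1.0)),  # mode > max
            ("uniform", (2.0, 1.0, None)),
        ],
    )
    def test_parameter_invariants(self, kind, params):
        with pytest.raises(ValueError):
            DistributionSpec(kind, *params)

    def test_lognormal_from_mean_roundtrip(self):
        spec = lognormal_from_mean(450.0, 1.5)
        assert spec.mean == pytest.approx(450.0)
        neg = lognormal_from_mean(-500.0, 1.3)
        assert neg.mean == pytest.approx(-500.0)


class TestSampling:
    def test_point_always_returns_value(self):
        spec = DistributionSpec("point", 42.0)
        r = np.random.default_rng(0)
        assert all(sample(spec, r) == 42.0 for _ in range(10))

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("lognormal", 1.0, 2.0),
            DistributionSpec("normal", 0.5, 0.1),
            DistributionSpec("triangular", 1.0, 2.0, 4.0),
            DistributionSpec("uniform", 2.0, 6.0),
        ],
        ids=lambda s: s.kind,
    )
    def test_sample_mean_matches_central_value(self, spec):
        r = np.random.default_rng(7)
        draws = sample(spec, r, size=100_000)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - spec.mean) < 3 * se

    def test_lognormal_support_positive(self):
        draws = sample(DistributionSpec("lognormal", 1.0, 3.0),
                       np.random.default_rng(1), size=10_000)
        assert (draws > 0).all()

    def test_mirrored_lognormal_negative(self):
        draws = sample(lognormal_from_mean(-500.0, 1.5),
                       np.random.default_rng(2), size=1000)
        assert (draws < 0).all()

    def test_sign_preserving_rejection(self):
        # normal(0.2, 1) puts 42% of mass below zero: rejection must keep
        # every draw on the central value's side
        draws = sample(DistributionSpec("normal", 0.2, 1.0),
                       np.random.default_rng(3), size=5000)
        assert (draws >= 0).all()

    def test_pathological_spec_rejected(self, monkeypatch):
        # if every redraw keeps the wrong sign the sampler must give up
        # rather than loop forever
        import relca.distributions as dists

        monkeypatch.setattr(
            dists, "_draw", lambda spec, rng, size: np.full(size, -1.0)
        )
        spec = DistributionSpec("normal", 0.5, 0.1)
        with pytest.raises(RuntimeError, match="rejection limit"):
            sample(spec, np.random.default_rng(4), size=100)


class TestBackCalcSigma:
    def test_printed_formula(self):
        assert back_calc_sigma(10.0, 20.0) == pytest.approx(10.0 / 3.29)

    def test_degenerate_range(self):
        assert back_calc_sigma(5.0, 5.0) == 0.0

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            back_calc_sigma(20.0, 10.0)

    def test_normal_quantile_roundtrip(self):
        # q95 - q05 = 2 * 1.6449 sigma; the rounded 1.645 recovers sigma
        # within 0.1%
        from scipy.stats import norm

        mu, sigma = 3.0, 1.7
        est = back_calc_sigma(norm.ppf(0.05, mu, sigma), norm.ppf(0.95, mu, sigma))
        assert est == pytest.approx(sigma, rel=1e-3)

    @given(
        st.floats(-1e6, 1e6),
        st.floats(0, 1e6),
        st.floats(-1e6, 1e6),
    )
    @settings(max_examples=50, derandomize=True)
    def test_translation_invariance(self, p05, width, shift):
        a = back_calc_sigma(p05, p05 + width)
        b = back_calc_sigma(p05 + shift, p05 + width + shift)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestCombineComponents:
    def test_no_dispersion_identity(self):
        base = DistributionSpec("lognormal", 5.0, 1.0)
        out = combine_components(base, DispersionComponents())
        assert out.p2 == pytest.approx(1.0)
        assert out.mean == pytest.approx(base.mean)

    def test_additive_ln_variance(self):
        # base ln-variance 1 plus three unit components: total 4, gsd e^2
        base = DistributionSpec("lognormal", 1.0, math.e)
        out = combine_components(base, DispersionComponents(1.0, 1.0, 1.0))
        assert out.p2 == pytest.approx(math.e**2)
        assert out.mean == pytest.approx(base.mean)

    def test_normal_zero_components_unchanged(self):
        base = DistributionSpec("normal", 10.0, 1.0)
        assert combine_components(base, DispersionComponents()) == base

    def test_normal_cv_addition(self):
        base = DistributionSpec("normal", 10.0, 1.0)  # cv 0.1
        out = combine_components(base, DispersionComponents(0.03, 0.0, 0.0))
        assert out.p1 == 10.0
        assert out.p2 == pytest.approx(10.0 * math.sqrt(0.01 + 0.03))

    def test_unsupported_kind_directs_to_refit(self):
        base = DistributionSpec("uniform", 0.0, 1.0)
        with pytest.raises(ValueError, match="refit"):
            combine_components(base, DispersionComponents(0.1, 0.0, 0.0))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            DispersionComponents(-0.1, 0.0, 0.0)


class TestFitDistribution:
    def test_lognormal_recovery(self):
        r = np.random.default_rng(42)
        x = r.lognormal(0.0, math.log(2.0), 200)
        spec, report = fit_distribution(x)
        assert spec.kind == "lognormal"
        assert report.selected == "lognormal"
        assert set(report.statistics) == {"lognormal", "normal", "triangular", "uniform"}

    def test_constant_samples_give_point(self):
        spec, report = fit_distribution([3.0] * 10)
        assert spec.kind == "point" and spec.p1 == 3.0
        assert report.selected == "point"

    def test_too_few_samples_refused(self):
        with pytest.raises(FittingError, match="minimum 5"):
            fit_distribution([1.0, 2.0, 3.0])

    def test_nonpositive_excludes_lognormal(self):
        r = np.random.default_rng(0)
        x = np.concatenate([r.normal(5, 1, 99), [0.0]])
        _, report = fit_distribution(x)
        assert report.excluded == {"lognormal": "non-positive samples"}

    def test_all_candidates_excluded(self):
        with pytest.raises(FittingError, match="excluded"):
            fit_distribution([0.0, 1.0, 2.0, 3.0, 4.0], candidates=("lognormal",))

    @pytest.mark.parametrize(
        "kind,make",
        [
            ("lognormal", lambda r: r.lognormal(0.0, math.log(2.0), 500)),
            ("normal", lambda r: r.normal(10.0, 3.0, 500)),
            ("triangular", lambda r: r.triangular(0.0, 0.3, 1.0, 500)),
            ("uniform", lambda r: r.uniform(0.0, 1.0, 500)),
        ],
    )
    def test_selection_consistency(self, kind, make):
        """AD selection recovers the generating family in >= 80% of seeded
        replications at n = 500."""
        hits = 0
        for seed in range(50):
            x = make(np.random.default_rng(seed))
            spec, _ = fit_distribution(x)
            hits += spec.kind == kind
        assert hits >= 40
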
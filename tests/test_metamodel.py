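"""Multilevel and classical REML: oracles, symmetries, heterogeneity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from conftest import simulate_effect_table
from dimorph.metamodel import (
    _design,
    fit_multilevel_reml,
    fit_random_effects,
    i2_multilevel,
    reml_loglik,
    typical_sampling_variance,
)


def brute_force_multilevel_loglik(y, v, strains, institutions) -> float:
    """Independent oracle: dense grid over the three variance components
    followed by Nelder-Mead refinement of the restricted log-likelihood."""
    Zs, Zl = _design(np.asarray(strains)), _design(np.asarray(institutions))
    nll = lambda s2: -reml_loglik(np.maximum(s2, 0), y, v, Zs, Zl)
    scale = max(np.var(y), v.mean())
    grid = np.concatenate([[0.0], np.geomspace(1e-5, 10 * scale, 12)])
    best, best_val = None, np.inf
    for s in itertools.product(grid, repeat=3):
        val = nll(np.array(s))
        if val < best_val:
            best_val, best = val, np.array(s)
    res = optimize.minimize(nll, best, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return -min(best_val, res.fun)


def _random_instance(rng):
    k = int(rng.integers(3, 13))
    return pd.DataFrame({
        "estimate": rng.normal(0.1, 0.15, k),
        "sampling_variance": rng.uniform(0.005, 0.05, k),
        "strain": rng.integers(0, rng.integers(2, 6), k),
        "institution": rng.integers(0, rng.integers(2, 6), k),
    })


class TestMultilevelREML:
    def test_degenerate_equal_effects(self):
        eff = pd.DataFrame({
            "estimate": [0.3] * 5, "sampling_variance": [0.01] * 5,
            "strain": list("aabbc"), "institution": list("xyxyx"),
        })
        r = fit_multilevel_reml(eff)
        assert r.mu_hat == pytest.approx(0.3, abs=1e-8)
        assert r.sigma2_strain + r.sigma2_location + r.sigma2_unit == pytest.approx(0, abs=1e-8)

    def test_fixed_effect_limit(self):
        """With all components at 0 the GLS mean is the inverse-variance mean."""
        rng = np.random.default_rng(0)
        eff = _random_instance(rng)
        y = eff["estimate"].to_numpy()
        v = eff["sampling_variance"].to_numpy()
        Zs, Zl = _design(eff["strain"].to_numpy()), _design(eff["institution"].to_numpy())
        from dimorph.metamodel import _gls_mean

        mu, _ = _gls_mean(np.zeros(3), y, v, Zs, Zl)
        assert mu == pytest.approx((y / v).sum() / (1 / v).sum(), rel=1e-12)

    def test_oracle_equivalence(self):
        """REML optimum matches brute-force maximisation on random instances."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            eff = _random_instance(rng)
            fit = fit_multilevel_reml(eff)
            oracle = brute_force_multilevel_loglik(
                eff["estimate"].to_numpy(), eff["sampling_variance"].to_numpy(),
                eff["strain"], eff["institution"],
            )
            assert abs(fit.loglik - oracle) <= 1e-6

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        eff = _random_instance(rng)
        base = fit_multilevel_reml(eff)
        shifted = eff.assign(estimate=eff["estimate"] + 0.7)
        r = fit_multilevel_reml(shifted)
        assert r.mu_hat == pytest.approx(base.mu_hat + 0.7, abs=1e-7)
        for fieldname in ("sigma2_strain", "sigma2_location", "sigma2_unit", "se"):
            assert getattr(r, fieldname) == pytest.approx(getattr(base, fieldname), abs=1e-7)

    def test_refuses_single_effect(self):
        eff = pd.DataFrame({"estimate": [0.1], "sampling_variance": [0.01],
                            "strain": ["a"], "institution": ["x"]})
        with pytest.raises(ValueError):
            fit_multilevel_reml(eff)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            r = fit_multilevel_reml(_random_instance(rng))
            assert r.ci_low <= r.mu_hat <= r.ci_high


class TestI2:
    def test_all_zero_components(self):
        v = np.array([0.01, 0.02, 0.03])
        out = i2_multilevel(0, 0, 0, v)
        assert out["i2_total"] == 0.0

    def test_unit_equals_typical_gives_half(self):
        v = np.array([0.01, 0.02, 0.03, 0.015])
        s2 = typical_sampling_variance(v)
        out = i2_multilevel(0, 0, s2, v)
        assert out["i2_total"] == pytest.approx(0.5, rel=1e-12)

    def test_permutation_invariance_of_total(self):
        v = np.array([0.01, 0.02, 0.03])
        a = i2_multilevel(0.1, 0.02, 0.005, v)["i2_total"]
        b = i2_multilevel(0.005, 0.1, 0.02, v)["i2_total"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            r = fit_multilevel_reml(_random_instance(rng))
            assert r.i2_strain + r.i2_location + r.i2_unit == pytest.approx(
                r.i2_total, abs=1e-10)
            assert 0 <= r.i2_total <= 1


class TestClassicalRandomEffects:
    def test_two_equal_values(self):
        r = fit_random_effects([0.2, 0.2], [0.01, 0.01])
        assert r.mean == pytest.approx(0.2, abs=1e-10)
        assert r.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_reml_matches_1d_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            k = int(rng.integers(3, 15))
            y = rng.normal(0, 0.3, k)
            v = rng.uniform(0.005, 0.05, k)
            r = fit_random_effects(y, v)
            from dimorph.metamodel import _re_reml_nll

            # oracle: iterated grid refinement, pure enumeration
            lo, hi = 0.0, max(4 * np.var(y), 0.5)
            for _round in range(4):
                grid = np.linspace(lo, hi, 2001)
                vals = np.array([_re_reml_nll(t, y, v) for t in grid])
                i = int(np.argmin(vals))
                lo = grid[max(i - 1, 0)]
                hi = grid[min(i + 1, len(grid) - 1)]
            best = vals.min()
            assert _re_reml_nll(r.tau2, y, v) - best <= 1e-8

    def test_heterogeneous_ci_wider_than_fixed(self):
        y = np.array([0.5, -0.4, 0.6, -0.5])
        v = np.full(4, 0.01)
        r = fit_random_effects(y, v)
        fixed_se = np.sqrt(1 / (1 / v).sum())
        assert r.tau2 > 0
        assert (r.ci_high - r.ci_low) > 2 * 1.96 * fixed_se

    def test_refuses_single_value(self):
        with pytest.raises(ValueError):
            fit_random_effects([0.1], [0.01])


class TestCalibration:
    """Parameter recovery and type-I calibration at study-like conditions
    (scaled down from the acceptance suite for speed)."""

    def test_recovery_bias_and_coverage(self):
        rng = np.random.default_rng(70)
        hits, ests = 0, []
        n = 150
        for _ in range(n):
            eff = simulate_effect_table(rng, 0.1, 0.004, 0.004, 0.004)
            r = fit_multilevel_reml(eff)
            ests.append(r.mu_hat)
            hits += r.ci_low <= 0.1 <= r.ci_high
        assert abs(np.mean(ests) - 0.1) <= 0.015
        assert 0.90 <= hits / n <= 0.99

    def test_null_type_i_error(self):
        rng = np.random.default_rng(71)
        sig, n = 0, 300
        for _ in range(n):
            eff = simulate_effect_table(rng, 0.0, 0.004, 0.004, 0.004)
            r = fit_multilevel_reml(eff)
            sig += (r.ci_low > 0) or (r.ci_high < 0)
        assert 0.02 <= sig / n <= 0.09
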
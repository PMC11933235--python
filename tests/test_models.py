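"""Model summaries, transforms, and the four model families."""

import numpy as np
import pandas as pd
import pytest

from turntaking import models as M
from turntaking.synthetic_data import simulate_bernoulli_glmm

TINY_SAMPLER = {"chains": 2, "iterations": 600, "warmup": 300}


class TestZTransform:
    def test_basic(self):
        z = M.z_transform([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="age"):
            M.z_transform([2.0, 2.0, 2.0], name="age")

    def test_idempotent(self, rng):
        x = rng.normal(3, 7, 50)
        z = M.z_transform(x)
        assert M.z_transform(z) == pytest.approx(z, abs=1e-12)


class TestTransformTiming:
    def test_zero_maps_to_zero(self):
        assert M.transform_timing(0.0) == 0.0

    def test_formula(self):
        assert M.transform_timing(-0.14) == pytest.approx(-np.log1p(0.14))
        assert M.transform_timing(0.74) == pytest.approx(np.log1p(0.74))

    def test_monotone_and_invertible(self, rng):
        t = np.sort(rng.uniform(-30, 30, 200))
        y = M.transform_timing(t)
        assert (np.diff(y) > 0).all()
        assert M.inverse_transform_timing(y) == pytest.approx(t, abs=1e-9)


class TestPosteriorSummary:
    def test_symmetric_draws_pd_half(self, rng):
        x = rng.standard_normal(4000)
        s = M.posterior_summary(x - np.median(x))
        assert s["pd"] == pytest.approx(50.0, abs=3.0)

    def test_all_positive_pd_100(self):
        s = M.posterior_summary(np.linspace(0.1, 5, 200))
        assert s["pd"] == 100.0

    def test_quantiles_of_1_to_100(self):
        x = np.arange(1, 101, dtype=float)
        s = M.posterior_summary(x)
        assert s["estimate"] == pytest.approx(50.5)
        lo, hi = s["cri_89"]
        assert lo == pytest.approx(np.quantile(x, 0.055))
        assert hi == pytest.approx(np.quantile(x, 0.945))

    def test_empty_and_short_draws_rejected(self):
        with pytest.raises(ValueError):
            M.posterior_summary([])
        with pytest.raises(ValueError):
            M.posterior_summary(np.ones(10))

    def test_pd_consistent_with_cri(self, rng):
        # when the 89% equal-tailed CrI excludes 0, pd must be >= 94.5
        for _ in range(20):
            x = rng.normal(rng.uniform(-1, 1), 0.5, 2000)
            s = M.posterior_summary(x)
            lo, hi = s["cri_89"]
            if lo > 0 or hi < 0:
                assert s["pd"] >= 94.5


class TestSpecs:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            M.ModelSpec(family="weibull", response="y")

    def test_interaction_members_must_be_fixed_effects(self):
        with pytest.raises(ValueError, match="interaction"):
            M.ModelSpec(
                family="bernoulli", response="y",
                fixed_effects=["a"], interactions=[("a", "b")],
            )

    def test_poisson_requires_offset(self):
        with pytest.raises(ValueError, match="offset"):
            M.ModelSpec(family="poisson_offset", response="y")

    def test_full_profile_draw_count(self):
        spec = M.model1_spec()
        kept = spec.sampler["chains"] * (
            spec.sampler["iterations"] - spec.sampler["warmup"]
        )
        assert kept == 12000

    def test_non_standardized_covariate_rejected(self):
        df = pd.DataFrame(
            {"x_z": [1.0, 2.0, 3.0, 4.0], "response": [0, 1, 0, 1],
             "interaction_id": [0, 0, 1, 1]}
        )
        spec = M.ModelSpec(
            family="bernoulli", response="response", fixed_effects=["x_z"],
            random_effects=["interaction_id"], sampler=TINY_SAMPLER,
        )
        with pytest.raises(ValueError, match="z-scored"):
            M.fit_model(spec, df, seed=0)


class TestFitting:
    def test_bernoulli_recovers_strong_slope(self):
        df = simulate_bernoulli_glmm(
            1500, {"intercept": -0.3, "x1": 0.8}, n_groups=60, group_sd=0.4, seed=5
        )
        spec = M.ModelSpec(
            family="bernoulli", response="response", fixed_effects=["x1"],
            random_effects=["interaction_id"], sampler=TINY_SAMPLER,
        )
        fit, diag = M.fit_model(spec, df, seed=1)
        s = fit.params["x1"]
        assert s["cri_89"][0] > 0.4
        assert s["pd"] == 100.0
        assert diag.n_divergences == 0

    def test_seeded_fits_identical(self):
        df = simulate_bernoulli_glmm(400, {"intercept": 0.0, "x1": 0.3},
                                     n_groups=20, seed=2)
        spec = M.ModelSpec(
            family="bernoulli", response="response", fixed_effects=["x1"],
            random_effects=["interaction_id"], sampler=TINY_SAMPLER,
        )
        fit_a, _ = M.fit_model(spec, df, seed=7)
        fit_b, _ = M.fit_model(spec, df, seed=7)
        assert fit_a.params == fit_b.params

    def test_multivariate_binary_joint_fit(self, rng):
        n = 600
        types = ["action_action", "action_signal", "signal_action", "signal_signal"]
        x = M.z_transform(rng.standard_normal(n))
        # recipient-age-like effect pushes the last type
        logits = np.column_stack([np.zeros(n)] * 3 + [0.9 * x])
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        codes = np.array([rng.choice(4, p=p) for p in probs])
        df = pd.DataFrame(
            {
                "x1": x,
                "type": [types[c] for c in codes],
                "interaction_id": rng.integers(30, size=n),
            }
        )
        spec = M.ModelSpec(
            family="multivariate_binary",
            response=[f"is_{t}" for t in types],
            fixed_effects=["x1"],
            random_effects=["interaction_id"],
            sampler=TINY_SAMPLER,
        )
        fit, diag = M.fit_model(spec, df, seed=3)
        assert fit.params["is_signal_signal::x1"]["estimate"] > 0.2
        assert abs(fit.params["is_action_action::x1"]["estimate"]) < \
            fit.params["is_signal_signal::x1"]["estimate"]
        # four responses, shared grouping: one sd per response block
        assert sum(k.endswith("sd__interaction_id") for k in fit.params) == 4

    def test_categorical_alternative_runs(self, rng):
        n = 300
        types = ["action_action", "action_signal", "signal_action", "signal_signal"]
        df = pd.DataFrame(
            {
                "x1": M.z_transform(rng.standard_normal(n)),
                "type": rng.choice(types, n),
                "interaction_id": rng.integers(20, size=n),
            }
        )
        spec = M.ModelSpec(
            family="categorical", response="type", fixed_effects=["x1"],
            random_effects=["interaction_id"], sampler=TINY_SAMPLER,
        )
        fit, _ = M.fit_model(spec, df, seed=4)
        # three non-reference levels, each with its own coefficients
        assert sum(k.endswith("::x1") for k in fit.params) == 3

    def test_gaussian_type_contrasts_sum_to_zero_coding(self, rng):
        n = 700
        types = ["action_action", "action_signal", "signal_action", "signal_signal"]
        eff = dict(zip(types, [-0.4, 0.1, 0.0, 0.3]))
        tt = rng.choice(types, n)
        df = pd.DataFrame(
            {
                "x1": M.z_transform(rng.standard_normal(n)),
                "type": tt,
                "timing_t": [eff[t] for t in tt] + rng.normal(0, 0.6, n),
                "interaction_id": rng.integers(40, size=n),
            }
        )
        spec = M.ModelSpec(
            family="gaussian", response="timing_t", fixed_effects=["x1"],
            random_effects=["interaction_id"], type_column="type",
            sampler=TINY_SAMPLER,
        )
        fit, _ = M.fit_model(spec, df, seed=5)
        # sum-to-zero: the three contrast estimates approximate the
        # deviations from the grand mean (which is ~0 here)
        est = [fit.params[f"type[{t}]"]["estimate"] for t in types[:3]]
        assert est[0] == pytest.approx(-0.4, abs=0.15)
        assert fit.params["sigma"]["estimate"] == pytest.approx(0.6, abs=0.1)
        # interaction columns with x1 exist for each contrast level
        assert "x1:type[action_action]" in fit.params


class TestEffectReport:
    def _fake_fit(self, lo, hi):
        draws = np.random.default_rng(0).uniform(lo, hi, (2, 500))
        params = {"x": M.posterior_summary(draws)}
        spec = M.ModelSpec(family="bernoulli", response="y", fixed_effects=[],
                           random_effects=[])
        return M.FitResult(params=params, draws={"x": draws}, spec=spec)

    def test_cri_excluding_zero_flagged(self):
        text, df = M.effect_report(self._fake_fit(0.5, 1.5))
        assert df.loc[0, "evidence"]
        assert "*" in text

    def test_cri_containing_zero_not_flagged(self):
        text, df = M.effect_report(self._fake_fit(-1.0, 1.0))
        assert not df.loc[0, "evidence"]

    def test_serialization_round_trip(self, tmp_path):
        _, df = M.effect_report(self._fake_fit(0.5, 1.5))
        p = tmp_path / "eff.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        assert back["estimate"].iloc[0] == pytest.approx(df["estimate"].iloc[0])
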
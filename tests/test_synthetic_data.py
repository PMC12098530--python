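"""Generator: spec table structure, intercept calibration, floors, cohort draws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit
from scipy.stats import binom

from lpp_select.synthetic_data import (
    BinaryDataset,
    DegenerateOutcomeWarning,
    GeneratorConfig,
    PredictorSpec,
    apply_prevalence_floor,
    calibrate_intercept,
    default_predictor_specs,
    generate_dataset,
    load_specs,
    save_specs,
    specs_from_records,
)


def _spec(name="a", prev=0.2, beta=0.0, cat="indicator"):
    return PredictorSpec(name=name, label=name, category=cat, prevalence=prev, beta=beta)


class TestPredictorSpec:
    def test_rejects_bad_prevalence_and_beta(self):
        with pytest.raises(ValueError):
            _spec(prev=0.0)
        with pytest.raises(ValueError):
            _spec(prev=1.0)
        with pytest.raises(ValueError):
            _spec(beta=np.inf)
        with pytest.raises(ValueError):
            _spec(cat="nope")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            specs_from_records(
                [
                    {"name": "a", "category": "severe", "prevalence": 0.1, "beta": 0.0},
                    {"name": "a", "category": "severe", "prevalence": 0.2, "beta": 0.0},
                ]
            )


class TestCalibrateIntercept:
    def test_all_null_betas_closed_form(self):
        specs = [_spec(name=f"x{i}", beta=0.0) for i in range(5)]
        assert calibrate_intercept(specs, 0.151) == pytest.approx(
            logit(0.151), abs=1e-14
        )
        assert calibrate_intercept(specs, 0.5) == 0.0

    def test_hits_target_with_nonzero_betas(self):
        specs = [
            _spec(name="a", prev=0.3, beta=np.log(4.0)),
            _spec(name="b", prev=0.05, beta=np.log(2.0)),
        ]
        b0 = calibrate_intercept(specs, 0.151, seed=3)
        # independent Monte-Carlo check of the achieved marginal prevalence
        rng = np.random.default_rng(99)
        X = rng.random((400_000, 2)) < np.array([0.3, 0.05])
        achieved = (1 / (1 + np.exp(-(b0 + X @ np.log([4.0, 2.0]))))).mean()
        assert achieved == pytest.approx(0.151, abs=0.005)

    def test_small_mc_budget_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept([_spec()], 0.2, n_mc=100)


class TestPrevalenceFloor:
    def test_examples(self):
        specs = [_spec(name="lo", prev=0.01), _spec(name="hi", prev=0.35)]
        floored = apply_prevalence_floor(specs, 0.10)
        assert floored[0].prevalence == 0.10
        floored30 = apply_prevalence_floor(specs, 0.30)
        assert floored30[1].prevalence == 0.35
        assert apply_prevalence_floor(specs, 0.0) == specs
        # input untouched, betas/names/order unchanged
        assert specs[0].prevalence == 0.01
        assert [s.name for s in floored] == ["lo", "hi"]
        assert [s.beta for s in floored] == [s.beta for s in specs]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        prev=st.floats(0.001, 0.999),
        f1=st.floats(0.0, 0.9),
        f2=st.floats(0.0, 0.9),
    )
    def test_idempotent_and_monotone(self, prev, f1, f2):
        specs = [_spec(prev=prev)]
        once = apply_prevalence_floor(specs, f1)
        assert apply_prevalence_floor(once, f1) == once
        lo, hi = sorted([f1, f2])
        assert (
            apply_prevalence_floor(specs, hi)[0].prevalence
            >= apply_prevalence_floor(specs, lo)[0].prevalence
        )


class TestGenerateDataset:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(specs=(_spec(),), intercept=-1.0, n=500, seed=7)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_empirical_prevalence_within_binomial_band(self):
        n = 100_000
        cfg = GeneratorConfig(
            specs=(_spec(prev=0.05),), intercept=-2.0, n=n, seed=11
        )
        count = generate_dataset(cfg).X[:, 0].sum()
        lo, hi = binom.ppf([0.0005, 0.9995], n, 0.05)
        assert lo <= count <= hi

    def test_positive_effect_raises_conditional_outcome_rate(self):
        cfg = GeneratorConfig(
            specs=(_spec(prev=0.3, beta=np.log(6.30)),), intercept=-2.5, n=100_000, seed=5
        )
        ds = generate_dataset(cfg)
        x = ds.X[:, 0].astype(bool)
        assert ds.y[x].mean() > ds.y[~x].mean()

    def test_null_model_prevalence_matches_intercept(self):
        # all betas zero: outcome prevalence = expit(intercept) within 4 MC SEs
        n = 50_000
        target = 0.151
        cfg = GeneratorConfig(
            specs=tuple(_spec(name=f"x{i}") for i in range(4)),
            intercept=float(logit(target)),
            n=n,
            seed=1,
        )
        se = np.sqrt(target * (1 - target) / n)
        assert generate_dataset(cfg).y.mean() == pytest.approx(target, abs=4 * se)

    def test_column_means_unbiased_over_seeds(self):
        prev = 0.07
        n, n_seeds = 400, 150
        means = [
            generate_dataset(
                GeneratorConfig(specs=(_spec(prev=prev),), intercept=-1.0, n=n, seed=s)
            ).X[:, 0].mean()
            for s in range(n_seeds)
        ]
        se = np.sqrt(prev * (1 - prev) / (n * n_seeds))
        assert np.mean(means) == pytest.approx(prev, abs=4 * se)

    def test_degenerate_outcome_warns(self):
        cfg = GeneratorConfig(specs=(_spec(),), intercept=-30.0, n=50, seed=0)
        with pytest.warns(DegenerateOutcomeWarning):
            ds = generate_dataset(cfg)
        assert ds.degenerate

    def test_latent_copula_preserves_marginals_and_correlates(self):
        R = np.array([[1.0, 0.7], [0.7, 1.0]])
        cfg = GeneratorConfig(
            specs=(_spec(name="a", prev=0.2), _spec(name="b", prev=0.2)),
            intercept=-1.0,
            n=50_000,
            seed=3,
            correlation=R,
        )
        ds = generate_dataset(cfg)
        assert ds.X.mean(axis=0) == pytest.approx([0.2, 0.2], abs=0.01)
        assert np.corrcoef(ds.X[:, 0], ds.X[:, 1])[0, 1] > 0.3


class TestIo:
    def test_cohort_csv_roundtrip(self, tmp_path):
        cfg = GeneratorConfig.default(seed=2, n=200, n_mc=10_000)
        ds = generate_dataset(cfg)
        path = tmp_path / "cohort.csv"
        ds.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("subject_id,") and header.endswith(",outcome")
        back = BinaryDataset.from_csv(path)
        assert back.names == ds.names
        assert np.array_equal(back.X, ds.X) and np.array_equal(back.y, ds.y)

    def test_spec_yaml_roundtrip_and_or_scale(self, tmp_path):
        specs = default_predictor_specs()
        path = tmp_path / "specs.yaml"
        save_specs(specs, path)
        assert load_specs(path) == specs
        # odds ratios on the natural scale convert to log scale on load
        rec = {"name": "z", "category": "severe", "prevalence": 0.1, "odds_ratio": 6.30}
        (spec,) = specs_from_records([rec])
        assert spec.beta == pytest.approx(np.log(6.30))
        with pytest.raises(ValueError):
            specs_from_records([dict(rec, beta=1.0)])
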
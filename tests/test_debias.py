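"""De-biasing GAM: accuracy metrics, priors, HSGP and sequential fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contactfatigue.data_model import build_design, split_waves
from contactfatigue.debias import (
    SEQUENTIAL_SCALES,
    HillPriorSpec,
    age_curve,
    baseline_coverage,
    fit_debias_model,
    informative_hill_priors,
    mape,
    sequential_fit,
)
from contactfatigue.fatigue import HillParams
from contactfatigue.hsgp import HSGPConfig
from contactfatigue.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_wave,
    simulate_contacts,
)

from conftest import FAST_MCMC

SMALL_HSGP = HSGPConfig(n_basis=12)


class TestMetrics:
    def test_mape_examples(self):
        assert mape([1, 2, 3], [1, 2, 3]) == 0.0
        assert mape([2.0, 4.0], [2.2, 4.4]) == pytest.approx(10.0)
        assert mape([2.0, 4.0], [3.0, 3.0]) == pytest.approx(37.5)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_mape_scale_invariant(self, c):
        b = np.array([1.0, 2.0, 5.0])
        e = np.array([1.5, 1.8, 6.0])
        assert mape(c * b, c * e) == pytest.approx(mape(b, e))

    def test_mape_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            mape([1.0, 0.0], [1.0, 1.0])

    def test_coverage_counting(self):
        b = np.arange(10, dtype=float)
        assert baseline_coverage(b, b - 1, b + 1) == 1.0
        assert baseline_coverage(b, b + 1, b + 2) == 0.0
        lo = np.where(b < 4, b - 1, b + 1)
        assert baseline_coverage(b, lo, b + 2) == pytest.approx(0.4)


class TestHillPriors:
    def test_informative_priors_use_printed_scales(self):
        pr = informative_hill_priors(0.88, -1.55, 0.94)
        assert (pr.gamma_center, pr.gamma_scale) == (0.88, 0.5)
        assert (pr.zeta_center, pr.zeta_scale) == (-1.55, 0.1)
        assert (pr.eta_center, pr.eta_scale) == (0.94, 0.1)

    def test_informative_priors_reject_nonpositive_centers(self):
        with pytest.raises(ValueError):
            informative_hill_priors(-0.1, 0.0, 1.0)
        with pytest.raises(ValueError):
            informative_hill_priors(0.5, 0.0, 0.0)

    def test_sequential_propagation_scales(self):
        assert SEQUENTIAL_SCALES == {"beta": 0.3, "gamma": 0.3,
                                     "zeta": 0.1, "eta": 0.1}


@pytest.fixture(scope="module")
def fatigue_wave():
    fat = {"sex:male": HillParams(0.88, -1.55, 0.94),
           "sex:female": HillParams(0.88, -1.55, 0.94)}
    cfg = GeneratorConfig(fatigue=fat, calendar_trend=None, rng_seed=77)
    probs = {0: 0.4, **{r: 0.6 / 12 for r in range(1, 13)}}
    rec = simulate_contacts(generate_wave(cfg, probs, n=900, seed=78), cfg, seed=79)
    return cfg, build_design(rec)


class TestDebiasFit:
    def test_unadjusted_fit_underestimates_with_planted_fatigue(self, fatigue_wave):
        cfg, ds = fatigue_wave
        un = fit_debias_model(ds, SMALL_HSGP, adjust=False, seed=1,
                              n_warmup=500, n_steps=400)
        first = ds.records[ds.records["repeat_count"] == 0].reset_index(drop=True)
        base = fit_debias_model(build_design(first), SMALL_HSGP, adjust=False,
                                seed=2, n_warmup=500, n_steps=400)
        bc = age_curve(base)["median"].to_numpy()
        uc = age_curve(un)["median"].to_numpy()
        # repeaters under-report, so the pooled unadjusted curve sits below
        # the first-timer baseline on average
        assert uc.mean() < bc.mean()

    def test_adjusted_fit_moves_curve_back_toward_baseline(self, fatigue_wave):
        cfg, ds = fatigue_wave
        first = ds.records[ds.records["repeat_count"] == 0].reset_index(drop=True)
        base = fit_debias_model(build_design(first), SMALL_HSGP, adjust=False,
                                seed=2, n_warmup=500, n_steps=400)
        b = age_curve(base)["median"].to_numpy()
        un = fit_debias_model(ds, SMALL_HSGP, adjust=False, seed=1,
                              n_warmup=500, n_steps=400)
        adj = fit_debias_model(ds, SMALL_HSGP,
                               fatigue_features=("sex:male", "sex:female"),
                               adjust=True, seed=3, n_warmup=700, n_steps=500)
        m_adj = mape(b, age_curve(adj)["median"].to_numpy())
        m_un = mape(b, age_curve(un)["median"].to_numpy())
        assert m_adj < m_un

    def test_hill_block_structure(self, fatigue_wave):
        _, ds = fatigue_wave
        fit = fit_debias_model(ds, SMALL_HSGP,
                               fatigue_features=("sex:male", "sex:female"),
                               adjust=True, seed=5, **FAST_MCMC)
        assert fit.stacked("gamma").shape[1] == 2
        assert (fit.stacked("gamma") > 0).all()
        assert fit.meta["fatigue_features"] == ["sex:male", "sex:female"]


class TestSequentialFit:
    def test_two_identical_waves_give_stable_means(self):
        cfg = GeneratorConfig(n_per_wave=350, n_waves=1, fatigue=None,
                              calendar_trend=None, rng_seed=55)
        rec = generate_cohort(cfg)
        rec2 = rec.copy()
        rec2["wave"] = 2
        both = pd.concat([rec, rec2], ignore_index=True)
        waves = split_waves(both)
        adj, un = sequential_fit(waves, fatigue_features=(), hsgp=SMALL_HSGP,
                                 seed=3, n_warmup=600, n_steps=400)
        b1 = np.atleast_1d(adj[0].mean("beta"))
        b2 = np.atleast_1d(adj[1].mean("beta"))
        assert np.max(np.abs(b1 - b2)) < 0.1
        assert len(un) == 2

    def test_wave_order_enforced(self):
        cfg = GeneratorConfig(n_per_wave=60, n_waves=2, rng_seed=5)
        waves = split_waves(generate_cohort(cfg))
        with pytest.raises(ValueError, match="order"):
            sequential_fit(waves[::-1], fatigue_features=(), hsgp=SMALL_HSGP,
                           seed=0, **FAST_MCMC)
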
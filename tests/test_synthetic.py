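"""Panel structure, observation noise and ground-truth bookkeeping of the
synthetic cohort generator."""

import json

import numpy as np
import pytest

from contactfatigue.data_model import build_design, preprocess
from contactfatigue.fatigue import HillParams, hill_effect
from contactfatigue.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_margins,
    generate_panel,
    generate_wave,
    simulate_contacts,
    true_log_intensity,
    write_truth,
)


class TestPanelStructure:
    def test_full_retention_keeps_everyone(self):
        cfg = GeneratorConfig(n_per_wave=50, n_waves=4, retention=1.0, rng_seed=1)
        panel = generate_panel(cfg)
        counts = panel.groupby("part_id").size()
        assert (counts == 4).all()
        # repeat count at wave w is w - 1 for an always-present participant
        assert (panel["repeat_count"] == panel["wave"] - 1).all()

    def test_zero_retention_gives_only_first_timers(self):
        cfg = GeneratorConfig(n_per_wave=50, n_waves=4, retention=0.0, rng_seed=1)
        panel = generate_panel(cfg)
        assert (panel["repeat_count"] == 0).all()

    def test_retention_rate_matches_binomial_oracle(self):
        cfg = GeneratorConfig(n_per_wave=500, n_waves=10, retention=0.7, rng_seed=5)
        panel = generate_panel(cfg)
        rates = []
        for w in range(1, 10):
            cur = set(panel.loc[panel["wave"] == w, "part_id"])
            nxt = set(panel.loc[panel["wave"] == w + 1, "part_id"])
            rates.append(len(cur & nxt) / len(cur))
        se = np.sqrt(0.7 * 0.3 / 500)
        assert abs(np.mean(rates) - 0.7) < 3 * se

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(n_waves=3, retention=0.0, recruit_to_quota=False)

    def test_generated_panel_passes_preprocessing_unchanged(self, small_cohort):
        _, rec = small_cohort
        out = preprocess(rec, seed=0)
        assert len(out) == len(rec)
        assert (out["repeat_count"].to_numpy() == rec["repeat_count"].to_numpy()).all()
        build_design(out)  # validates all categories

    def test_repeat_mixture_of_cross_section(self):
        cfg = GeneratorConfig(rng_seed=2)
        probs = {0: 0.5, 3: 0.3, 10: 0.2}
        wave = generate_wave(cfg, probs, n=4000, seed=3)
        freq = wave["repeat_count"].value_counts(normalize=True)
        for r, p in probs.items():
            assert abs(freq[r] - p) < 3 * np.sqrt(p * (1 - p) / 4000)


class TestObservationModel:
    def test_negbin_variance_contract(self):
        # fixed lambda = 4, phi = 2 -> variance 4 + 16/2 = 12
        cfg = GeneratorConfig(n_per_wave=50_000, n_waves=1, beta0=float(np.log(4)),
                              effects={}, age_profile=None, calendar_trend=None,
                              fatigue=None, phi=2.0, truncate=False, rng_seed=8)
        rec = generate_cohort(cfg)
        assert abs(rec["y"].mean() - 4.0) < 0.1
        assert abs(rec["y"].var() - 12.0) < 0.6

    def test_poisson_limit_recovers_exp_beta0(self):
        cfg = GeneratorConfig(n_per_wave=30_000, n_waves=1, beta0=1.0, effects={},
                              age_profile=None, calendar_trend=None, fatigue=None,
                              observation="poisson", truncate=False, rng_seed=8)
        rec = generate_cohort(cfg)
        assert abs(rec["y"].mean() - np.e) < 0.05

    def test_fatigue_ratio_matches_hill_asymptote(self):
        # gamma = 0.9 with instant saturation: repeaters report e^-0.9 of
        # the first-timer mean for identical covariates
        fat = HillParams(gamma=0.9, zeta=10.0, eta=1.0)
        cfg = GeneratorConfig(n_per_wave=50_000, n_waves=1, beta0=float(np.log(4)),
                              effects={}, age_profile=None, calendar_trend=None,
                              fatigue=fat, truncate=False, rng_seed=8)
        wave = generate_wave(cfg, {0: 0.5, 8: 0.5}, n=100_000, seed=4)
        rec = simulate_contacts(wave, cfg, seed=5)
        m0 = rec.loc[rec["repeat_count"] == 0, "y"].mean()
        mr = rec.loc[rec["repeat_count"] == 8, "y"].mean()
        assert abs(mr / m0 - np.exp(-0.9)) < 0.02

    def test_fatigue_expected_count_non_increasing_in_r(self):
        cfg = GeneratorConfig(rng_seed=1)
        rec = generate_wave(cfg, {r: 1.0 for r in range(10)}, n=200, seed=2)
        base = rec.assign(repeat_count=0)
        for r in range(1, 10):
            lo = true_log_intensity(base.assign(repeat_count=r), cfg)
            hi = true_log_intensity(base.assign(repeat_count=r - 1), cfg)
            assert (lo <= hi + 1e-12).all()

    def test_no_fatigue_means_equal_expectation_across_r(self):
        cfg = GeneratorConfig(fatigue=None, rng_seed=1)
        rec = generate_wave(cfg, {0: 0.5, 5: 0.5}, n=200, seed=2)
        eta0 = true_log_intensity(rec.assign(repeat_count=0), cfg)
        eta5 = true_log_intensity(rec.assign(repeat_count=5), cfg)
        np.testing.assert_allclose(eta0, eta5)


class TestMargins:
    def test_zero_skew_proportional_to_sample(self, small_cohort):
        _, rec = small_cohort
        m = generate_margins(rec, total=1000.0, skew=0.0)
        counts = m.cells.set_index(["age_group", "sex", "hh_size"])["count"]
        assert abs(m.total - 1000.0) < 1e-6
        top = counts.idxmax()
        # most common sample cell gets the largest margin share
        from contactfatigue.poststrat import _cells
        sample = _cells(rec).value_counts()
        assert "|".join(top) == sample.idxmax()

    def test_skewed_margins_sum_to_total(self, small_cohort):
        _, rec = small_cohort
        m = generate_margins(rec, total=5e6, skew=0.8, seed=3)
        assert abs(m.total - 5e6) < 1e-3
        assert (m.cells["count"] >= 0).all()


def test_truth_file_round_trips_parameters(tmp_path):
    cfg = GeneratorConfig(n_per_wave=10, n_waves=2, rng_seed=4)
    path = tmp_path / "truth.json"
    write_truth(cfg, path)
    truth = json.loads(path.read_text())
    assert truth["fatigue"] == {"gamma": 0.88, "zeta": -1.55, "eta": 0.94}
    assert truth["phi"] == 2.0
    assert truth["n_per_wave"] == 10
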
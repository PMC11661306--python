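"""Post-stratification weights, bootstrap comparator and reporting."""

import numpy as np
import pandas as pd
import pytest

from contactfatigue.poststrat import (
    WeightedEstimate,
    bootstrap_mean,
    population_mean_intensity,
    poststrat_weights,
    subgroup_estimates,
    write_report,
)
from contactfatigue.sampling import PosteriorSummary
from contactfatigue.schema import AGE_MAX
from contactfatigue.synthetic import PopulationMargins, generate_margins

from conftest import make_records


def margins_from(cells):
    return PopulationMargins(cells=pd.DataFrame(cells))


def intercept_only_summary(beta0_draws):
    """Debias-style summary with no covariates and a flat age effect."""
    b0 = np.asarray(beta0_draws, dtype=float).reshape(2, -1)
    n_draw = b0.shape[1]
    draws = {
        "beta0": b0,
        "beta": np.zeros((2, n_draw, 0)),
        "f_grid": np.zeros((2, n_draw, AGE_MAX + 1)),
    }
    summ = PosteriorSummary(draws=draws, table=pd.DataFrame())
    summ.meta["beta_names"] = []
    return summ


class TestWeights:
    def test_proportional_margins_give_unit_weights(self, small_cohort):
        _, rec = small_cohort
        m = generate_margins(rec, total=1e6, skew=0.0)
        w = poststrat_weights(rec, m)
        np.testing.assert_allclose(w, 1.0)

    def test_two_cell_hand_computation(self):
        rec = make_records([{"age": 30, "part_id": "a"},
                            {"age": 50, "part_id": "b"}])
        m = margins_from([
            {"age_group": "25-34", "sex": "male", "hh_size": "2", "count": 80},
            {"age_group": "45-54", "sex": "male", "hh_size": "2", "count": 20},
        ])
        w = poststrat_weights(rec, m)
        np.testing.assert_allclose(w, [1.6, 0.4])

    def test_weights_positive_mean_one(self, small_cohort):
        _, rec = small_cohort
        m = generate_margins(rec, total=1e6, skew=0.5, seed=2)
        w = poststrat_weights(rec, m)
        assert (w > 0).all()
        assert w.mean() == pytest.approx(1.0)

    def test_empty_sample_cell_warns_and_renormalizes(self):
        rec = make_records([{"age": 30}])
        m = margins_from([
            {"age_group": "25-34", "sex": "male", "hh_size": "2", "count": 50},
            {"age_group": "75-79", "sex": "female", "hh_size": "1", "count": 50},
        ])
        with pytest.warns(UserWarning, match="redistributed"):
            w = poststrat_weights(rec, m)
        np.testing.assert_allclose(w, [1.0])

    def test_sample_cell_missing_from_margins_is_an_error(self):
        rec = make_records([{"age": 30}])
        m = margins_from([{"age_group": "45-54", "sex": "male",
                           "hh_size": "2", "count": 50}])
        with pytest.raises(ValueError, match="lack"):
            poststrat_weights(rec, m)


class TestPopulationEstimates:
    def test_intercept_only_model_collapses_to_exp_beta0(self):
        rng = np.random.default_rng(0)
        b0 = rng.normal(1.0, 0.05, size=400)
        summ = intercept_only_summary(b0)
        rec = make_records([{"part_id": f"p{i}", "age": 20 + i} for i in range(5)])
        est = population_mean_intensity(summ, rec)
        assert est.point == pytest.approx(np.median(np.exp(b0)), rel=1e-6)
        assert est.lower <= est.point <= est.upper

    def test_whole_population_subgroup_matches_population_estimate(self):
        rng = np.random.default_rng(1)
        summ = intercept_only_summary(rng.normal(0.8, 0.1, size=400))
        rec = make_records([{"part_id": f"p{i}", "age": 20 + 2 * i,
                             "sex": "male" if i % 2 else "female"}
                            for i in range(8)])
        pop = population_mean_intensity(summ, rec)
        sub = subgroup_estimates(summ, rec, {"all": {}})[0]
        assert sub.point == pytest.approx(pop.point)

    def test_disjoint_subgroups_recompose_population(self):
        rng = np.random.default_rng(2)
        summ = intercept_only_summary(rng.normal(0.8, 0.1, size=400))
        rec = make_records([{"part_id": f"p{i}", "age": 25,
                             "sex": "male" if i < 6 else "female"}
                            for i in range(10)])
        pop = population_mean_intensity(summ, rec)
        subs = subgroup_estimates(summ, rec, {"m": {"sex": "male"},
                                              "f": {"sex": "female"}})
        recomposed = 0.6 * subs[0].point + 0.4 * subs[1].point
        assert recomposed == pytest.approx(pop.point, rel=0.02)

    def test_unknown_subgroup_factor_rejected(self):
        summ = intercept_only_summary(np.zeros(4))
        rec = make_records([{}])
        with pytest.raises(ValueError, match="unknown factor"):
            subgroup_estimates(summ, rec, {"bad": {"planet": "mars"}})


class TestBootstrap:
    def test_constant_data_gives_point_mass(self):
        rec = make_records([{"part_id": f"p{i}", "y": 4} for i in range(30)])
        est = bootstrap_mean(rec, B=500, seed=1)
        assert (est.point, est.lower, est.upper) == (4.0, 4.0, 4.0)

    def test_seeded_runs_bit_identical(self):
        rng = np.random.default_rng(3)
        rec = make_records([{"part_id": f"p{i}", "y": int(v)}
                            for i, v in enumerate(rng.integers(0, 10, 200))])
        a = bootstrap_mean(rec, B=300, seed=9)
        b = bootstrap_mean(rec, B=300, seed=9)
        assert (a.point, a.lower, a.upper) == (b.point, b.lower, b.upper)

    def test_interval_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        widths = []
        for n in (100, 400, 1600):
            rec = make_records([{"part_id": f"p{i}", "y": int(v)}
                                for i, v in enumerate(rng.poisson(3, n))])
            est = bootstrap_mean(rec, B=2000, seed=11)
            widths.append(est.upper - est.lower)
        # CLT: width ~ 1/sqrt(n), so each quadrupling halves the width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.35)

    def test_rejects_repeaters_and_warns_on_small_B(self):
        rec = make_records([{"part_id": "a", "repeat_count": 1, "y": 2}])
        with pytest.raises(ValueError):
            bootstrap_mean(rec, B=500)
        ok = make_records([{"part_id": "a", "y": 2}])
        with pytest.warns(UserWarning, match="resamples"):
            bootstrap_mean(ok, B=50, seed=0)

    def test_converges_to_weighted_sample_mean(self):
        rng = np.random.default_rng(5)
        rec = make_records([{"part_id": f"p{i}", "y": int(v)}
                            for i, v in enumerate(rng.poisson(3, 300))])
        w = rng.uniform(0.5, 2.0, 300)
        est = bootstrap_mean(rec, B=10_000, seed=2, weights=w)
        target = float(np.average(rec["y"], weights=w))
        assert abs(est.point - target) < 0.01


class TestReport:
    def test_empty_results_give_header_only(self, tmp_path):
        path = tmp_path / "est.csv"
        write_report([], path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["wave", "method", "subgroup",
                                       "point", "lower", "upper"]
        assert len(frame) == 0

    def test_round_trip_and_stringency_overlay(self, tmp_path):
        ests = [WeightedEstimate(3.1, 2.8, 3.5, wave=1, method="adjusted"),
                WeightedEstimate(2.7, 2.4, 3.0, wave=2, method="unadjusted")]
        strn = pd.DataFrame({"wave": [1, 2], "index": [70.0, 55.0]})
        path = tmp_path / "est.csv"
        out = write_report(ests, path, stringency=strn)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, out)
        assert back["stringency"].tolist() == [70.0, 55.0]

    def test_estimate_invariant(self):
        with pytest.raises(ValueError):
            WeightedEstimate(5.0, 1.0, 4.0)
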
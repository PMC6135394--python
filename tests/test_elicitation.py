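"""Probit scaling, anchoring, loess mapping and uncertainty propagation.

The derived expectations here come from independent oracles: a grid search
of the exact probit log-likelihood, a brute-force tricube-weighted local
least squares, and the closed-form logit-normal quantile function.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from waly.catalogue import Catalogue, WelfareImpediment
from waly.elicitation import (
    AnchorSet,
    ElicitationError,
    IWWEstimate,
    ProbitScale,
    anchor_iww_from_tto,
    anchor_iww_from_vas,
    check_rank_consistency,
    elicit_iwws,
    fit_anchor_map,
    fit_probit_scale,
    inv_logit,
    logit,
    predict_iwws,
    propagate_iww_uncertainty,
    run_variants,
    subgroup_compare,
)
from waly.survey import AnchorResponse, PairedDesignRow, RespondentProfile


def _rows(pairs_outcomes):
    return [
        PairedDesignRow("r", f"q{k}", a, b, y)
        for k, (a, b, y) in enumerate(pairs_outcomes)
    ]


class TestProbitScale:
    def test_balanced_choices_give_zero_gap(self):
        rows = _rows([("a", "b", 1)] * 50 + [("a", "b", 0)] * 50)
        scale = fit_probit_scale(rows, reference="a")
        assert scale.coefficients["a"] == 0.0
        assert scale.coefficients["b"] == pytest.approx(0.0, abs=1e-6)

    def test_recovers_latent_gaps_against_grid_search_oracle(self):
        # severities 0, 1, 3: latent gaps 1.0 and 2.0
        truth = {"a": 0.0, "b": 1.0, "c": 3.0}
        rng = np.random.default_rng(42)
        rows = []
        n = 5000
        for first, second in itertools.combinations("abc", 2):
            p_first_better = stats.norm.cdf(truth[second] - truth[first])
            y = rng.random(n) < p_first_better
            rows += [
                PairedDesignRow("r", f"{first}{second}{k}", first, second,
                                int(v))
                for k, v in enumerate(y)
            ]
        scale = fit_probit_scale(rows, reference="a", ridge_alpha=0.0)

        # oracle: exact probit log-likelihood maximised by grid search
        counts = {}
        for r in rows:
            key = (r.first_impediment, r.second_impediment)
            w, t = counts.get(key, (0, 0))
            counts[key] = (w + r.outcome, t + 1)

        def loglik(bb, bc):
            s = {"a": 0.0, "b": bb, "c": bc}
            ll = 0.0
            for (f, sec), (wins, tot) in counts.items():
                p = stats.norm.cdf(s[sec] - s[f])
                ll += wins * math.log(p) + (tot - wins) * math.log(1 - p)
            return ll

        grid = np.arange(-0.5, 0.51, 0.01)
        best = max(
            ((truth["b"] + db, truth["c"] + dc) for db in grid for dc in grid),
            key=lambda t: loglik(*t),
        )
        assert scale.coefficients["b"] == pytest.approx(best[0], abs=0.02)
        assert scale.coefficients["c"] == pytest.approx(best[1], abs=0.02)
        for imp in "bc":
            se = scale.standard_errors[imp]
            assert abs(scale.coefficients[imp] - truth[imp]) < 3 * se

    def test_full_survey_yields_finite_coefficients(self, design, catalogue):
        ref = design[0].first_impediment
        scale = fit_probit_scale(design, reference=ref)
        assert len(scale.coefficients) == 35
        assert scale.coefficients[ref] == 0.0
        assert all(np.isfinite(v) for v in scale.coefficients.values())

    def test_pure_ml_errors_on_perfect_separation(self):
        # one impediment judged better in every comparison (hence least
        # severe): unpenalized ML has no finite optimum, the contrast-
        # ridge fit stays finite
        rows = _rows([("a", "b", 0)] * 30 + [("b", "c", 1)] * 30
                     + [("a", "c", 1)] * 15 + [("a", "c", 0)] * 15)
        with pytest.raises(ElicitationError, match="separation"):
            fit_probit_scale(rows, reference="a", ridge_alpha=0.0)
        scale = fit_probit_scale(rows, reference="a")
        assert np.isfinite(scale.coefficients["b"])
        assert scale.coefficients["b"] < scale.coefficients["a"]
        assert scale.coefficients["b"] < scale.coefficients["c"]

    def test_disconnected_graph_rejected(self):
        rows = _rows([("a", "b", 1)] * 5 + [("c", "d", 0)] * 5)
        with pytest.raises(ElicitationError, match="disconnected"):
            fit_probit_scale(rows, reference="a")

    def test_unknown_reference_rejected(self):
        rows = _rows([("a", "b", 1)])
        with pytest.raises(ElicitationError, match="reference"):
            fit_probit_scale(rows, reference="zzz")


class TestAnchorFormulae:
    def test_vas_mean_of_complement(self):
        responses = [
            AnchorResponse("r1", "vas", "fever", 70.0),
            AnchorResponse("r2", "vas", "fever", 80.0),
        ]
        entries = anchor_iww_from_vas(responses).entries
        assert entries["fever"][0] == pytest.approx(0.25)
        assert entries["fever"][2] == 2

    @pytest.mark.parametrize("value,expected", [(100.0, 0.0), (0.0, 1.0)])
    def test_vas_boundaries(self, value, expected):
        entries = anchor_iww_from_vas(
            [AnchorResponse("r", "vas", "fever", value)]
        ).entries
        assert entries["fever"][0] == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values,expected", [([10.0], 0.0), ([5.0, 5.0], 0.5), ([0.0], 1.0)]
    )
    def test_tto_traded_years(self, values, expected):
        responses = [
            AnchorResponse(f"r{k}", "tto", "fever", v)
            for k, v in enumerate(values)
        ]
        entries = anchor_iww_from_tto(responses).entries
        assert entries["fever"][0] == pytest.approx(expected)

    def test_shift_linearity(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(20, 70, 12)
        a0 = anchor_iww_from_vas(
            [AnchorResponse(f"r{k}", "vas", "fever", v)
             for k, v in enumerate(base)]
        ).entries["fever"][0]
        a1 = anchor_iww_from_vas(
            [AnchorResponse(f"r{k}", "vas", "fever", v + 10)
             for k, v in enumerate(base)]
        ).entries["fever"][0]
        assert a1 == pytest.approx(a0 - 0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ElicitationError, match="filter"):
            anchor_iww_from_tto([AnchorResponse("r", "tto", "fever", 12.0)])


def _scale(coefs, reference):
    return ProbitScale(
        coefficients=coefs,
        standard_errors={k: 0.1 for k in coefs},
        reference_impediment_id=reference,
        n_rows=100,
    )


def _anchor_set(means, method="tto"):
    return AnchorSet(
        method=method,
        entries={k: (v, 0.05, 30) for k, v in means.items()},
    )


class TestAnchorMap:
    def test_exactly_linear_anchors_are_reproduced(self):
        coefs = {"a": 0.0, "b": 0.5, "c": 1.0, "d": 1.5, "e": 2.0}
        means = {k: float(inv_logit(-1.0 + 1.2 * c)) for k, c in coefs.items()}
        mapping = fit_anchor_map(_scale(coefs, "a"), _anchor_set(means))
        for k, c in coefs.items():
            mean, se = mapping.predict(c)
            assert mean == pytest.approx(float(logit(means[k])), abs=1e-8)
            assert se == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_tricube_local_least_squares(self):
        rng = np.random.default_rng(5)
        x = np.array([0.0, 0.7, 1.4, 2.1, 3.0])
        y = -0.5 + 0.8 * x + rng.normal(0, 0.15, 5)
        means = {f"i{k}": float(inv_logit(v)) for k, v in enumerate(y)}
        coefs = {f"i{k}": float(v) for k, v in enumerate(x)}
        mapping = fit_anchor_map(_scale(coefs, "i0"), _anchor_set(means))
        span = mapping.span
        n = len(x)
        q = max(4, math.ceil(span * n))
        for x0 in x:
            d = np.abs(x - x0)
            dmax = np.sort(d)[q - 1]
            w = np.zeros(n)
            near = np.argsort(d, kind="stable")[:q]
            w[near] = (1 - (d[near] / dmax) ** 3) ** 3
            # brute-force weighted least squares via sqrt-weight design
            sw = np.sqrt(w)
            A = np.column_stack([sw, sw * (x - x0)])
            coef, *_ = np.linalg.lstsq(A, sw * np.log(
                np.array([means[f"i{k}"] for k in range(n)])
                / (1 - np.array([means[f"i{k}"] for k in range(n)]))
            ), rcond=None)
            assert mapping.predict(float(x0))[0] == pytest.approx(
                coef[0], abs=1e-8
            )

    def test_exclusion_variant_recorded_and_fits(self):
        coefs = {"a": 0.0, "b": 0.5, "respiratory_distress": 2.0,
                 "c": 1.0, "d": 1.5}
        means = {"a": 0.2, "b": 0.35, "c": 0.5, "d": 0.65,
                 "respiratory_distress": 0.85}
        anchors = _anchor_set(means).exclude("respiratory_distress")
        assert anchors.excluded_anchor == "respiratory_distress"
        mapping = fit_anchor_map(_scale(coefs, "a"), anchors)
        assert len(mapping.x) == 4

    def test_fewer_than_two_anchors_rejected(self):
        with pytest.raises(ElicitationError, match="two anchors"):
            fit_anchor_map(_scale({"a": 0.0}, "a"), _anchor_set({"a": 0.5}))

    def test_identical_coefficients_rejected(self):
        coefs = {"a": 0.0, "b": 0.0}
        with pytest.raises(ElicitationError, match="identical"):
            fit_anchor_map(
                _scale(coefs, "a"), _anchor_set({"a": 0.3, "b": 0.6})
            )


class TestPredictIwws:
    def test_prediction_at_anchor_coefficient_exact_for_linear_anchors(self):
        coefs = {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0, "x": 1.0}
        means = {k: float(inv_logit(-1 + 0.9 * coefs[k]))
                 for k in ("a", "b", "c", "d")}
        mapping = fit_anchor_map(_scale(coefs, "a"), _anchor_set(means))
        preds = predict_iwws(mapping, _scale(coefs, "a"))
        assert preds["x"][0] == pytest.approx(float(logit(means["b"])),
                                              abs=1e-8)

    def test_monotone_anchors_give_monotone_predictions(self):
        coefs = {f"i{k}": 0.5 * k for k in range(5)}
        means = {k: float(inv_logit(-1.5 + 1.1 * c))
                 for k, c in coefs.items()}
        mapping = fit_anchor_map(_scale(coefs, "i0"), _anchor_set(means))
        grid = np.linspace(0, 2.0, 9)
        preds = [mapping.predict(float(g))[0] for g in grid]
        assert all(a <= b + 1e-12 for a, b in zip(preds, preds[1:]))

    def test_one_prediction_per_impediment(self, design, scenario):
        ref = design[0].first_impediment
        scale = fit_probit_scale(design, reference=ref)
        anchors = anchor_iww_from_tto(
            [a for a in scenario.anchors if a.method == "tto" and a.feasible]
        )
        mapping = fit_anchor_map(scale, anchors)
        preds = predict_iwws(mapping, scale)
        assert set(preds) == set(scale.coefficients)


class TestPropagation:
    def test_zero_se_collapses_interval(self):
        (est,) = propagate_iww_uncertainty({"a": (0.7, 0.0)}, 100, seed=1)
        expected = float(inv_logit(0.7))
        assert est.ui_low == est.mean == est.ui_high == expected

    def test_symmetric_logit_normal_centres_on_half(self):
        (est,) = propagate_iww_uncertainty({"a": (0.0, 1.0)}, 100_000, seed=2)
        assert est.mean == pytest.approx(0.5, abs=0.005)

    def test_percentiles_match_logit_normal_quantiles(self):
        mu, se = -0.4, 0.7
        (est,) = propagate_iww_uncertainty({"a": (mu, se)}, 100_000, seed=3)
        q_low = float(inv_logit(stats.norm.ppf(0.025, mu, se)))
        q_high = float(inv_logit(stats.norm.ppf(0.975, mu, se)))
        assert est.ui_low == pytest.approx(q_low, abs=0.005)
        assert est.ui_high == pytest.approx(q_high, abs=0.005)

    def test_negative_se_rejected(self):
        with pytest.raises(ElicitationError, match="negative"):
            propagate_iww_uncertainty({"a": (0.0, -1.0)}, 10)

    def test_fixed_seed_reproduces(self):
        a = propagate_iww_uncertainty({"a": (0.1, 0.4)}, 1000, seed=9)
        b = propagate_iww_uncertainty({"a": (0.1, 0.4)}, 1000, seed=9)
        assert a == b


class TestPipeline:
    def test_reference_invariance(self, design, scenario):
        anchors = anchor_iww_from_tto(
            [a for a in scenario.anchors if a.method == "tto" and a.feasible]
        )
        tables = []
        for ref in ("anaemia_mild", "fever"):
            est = elicit_iwws(
                design, anchors, variant="minus_respiratory_distress",
                reference=ref, n_sims=1000, seed=0,
            )
            tables.append({e.impediment_id: e.mean for e in est})
        diffs = [abs(tables[0][k] - tables[1][k]) for k in tables[0]]
        assert max(diffs) < 1e-6

    def test_six_variants_full_shape(self, design, scenario):
        feasible = [a for a in scenario.anchors if a.feasible]
        tables = run_variants(
            design,
            anchor_iww_from_vas(feasible),
            anchor_iww_from_tto(feasible),
            n_sims=500, seed=0,
        )
        assert len(tables) == 6
        for (method, variant), est in tables.items():
            assert method in ("vas", "tto")
            assert len(est) == 35
            for e in est:
                assert 0.0 <= e.ui_low <= e.mean <= e.ui_high <= 1.0

    def test_variants_deterministic_under_seed(self, design, scenario):
        feasible = [a for a in scenario.anchors if a.feasible]
        kw = dict(n_sims=200, seed=5)
        a = run_variants(design, anchor_iww_from_vas(feasible),
                         anchor_iww_from_tto(feasible), **kw)
        b = run_variants(design, anchor_iww_from_vas(feasible),
                         anchor_iww_from_tto(feasible), **kw)
        assert a == b


class TestRankConsistency:
    def test_concordant_data_empty_report(self):
        coefs = {"a": 0.0, "b": 1.0, "c": 2.0}
        report = check_rank_consistency(
            _scale(coefs, "a"), _anchor_set({"a": 0.2, "b": 0.5, "c": 0.8})
        )
        assert report == []

    def test_single_swap_flagged_once(self):
        coefs = {"a": 0.0, "b": 1.0, "c": 2.0}
        report = check_rank_consistency(
            _scale(coefs, "a"), _anchor_set({"a": 0.2, "b": 0.8, "c": 0.5})
        )
        assert len(report) == 1
        pair = {report[0].impediment_a, report[0].impediment_b}
        assert pair == {"b", "c"}

    def test_lung_metastasis_versus_respiratory_distress_scenario(self):
        # paired comparison ranks the metastasis above respiratory distress,
        # both anchor methods rank it below: exactly one inconsistency
        coefs = {
            "anaemia_mild": 0.0,
            "msk_one_limb_mild": 0.8,
            "diarrhoea_frequent": 1.2,
            "respiratory_distress": 2.4,
            "cancer_lung_metastasis": 2.7,
        }
        anchors = _anchor_set(
            {
                "anaemia_mild": 0.20,
                "msk_one_limb_mild": 0.39,
                "diarrhoea_frequent": 0.48,
                "cancer_lung_metastasis": 0.86,
                "respiratory_distress": 0.92,
            }
        )
        report = check_rank_consistency(_scale(coefs, "anaemia_mild"), anchors)
        assert len(report) == 1
        assert {report[0].impediment_a, report[0].impediment_b} == {
            "respiratory_distress", "cancer_lung_metastasis"
        }


def _profiles(n_a, n_b, grouping_value):
    out = []
    for k in range(n_a + n_b):
        female = k < n_a
        out.append(
            RespondentProfile(
                respondent_id=f"r{k}",
                gender="female" if female else "male",
                age=30.0,
                graduation_year=2010,
                interest_small_animal=True,
                works_with_livestock=False,
                questionnaire_version="C",
            )
        )
    return out


class TestSubgroupCompare:
    def test_identical_groups_not_significant(self):
        profiles = _profiles(3, 3, "gender")
        anchors = [
            AnchorResponse(p.respondent_id, "vas", "fever", 40.0)
            for p in profiles
        ]
        (rec,) = subgroup_compare(anchors, profiles, "gender")
        assert rec["t"] == 0.0 and rec["p_value"] == 1.0
        assert not rec["significant"]

    def test_separated_zero_variance_groups_significant(self):
        profiles = _profiles(3, 3, "gender")
        anchors = [
            AnchorResponse(p.respondent_id, "vas", "fever",
                           80.0 if p.gender == "female" else 20.0)
            for p in profiles
        ]
        (rec,) = subgroup_compare(anchors, profiles, "gender")
        assert rec["significant"]
        assert rec["mean_a"] == pytest.approx(0.2)
        assert rec["mean_b"] == pytest.approx(0.8)

    def test_small_group_skipped_with_reason(self):
        profiles = _profiles(1, 3, "gender")
        anchors = [
            AnchorResponse(p.respondent_id, "vas", "fever", 40.0)
            for p in profiles
        ]
        (rec,) = subgroup_compare(anchors, profiles, "gender")
        assert rec["skipped"] is not None
        assert not rec["significant"]

    def test_null_false_positive_rate_near_alpha(self):
        # no true group difference at n=20/20: the Welch test should reject
        # at close to its nominal 5% level
        rng = np.random.default_rng(77)
        profiles = _profiles(20, 20, "gender")
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            anchors = [
                AnchorResponse(p.respondent_id, "vas", "fever",
                               float(np.clip(rng.normal(50, 15), 0, 100)))
                for p in profiles
            ]
            (rec,) = subgroup_compare(anchors, profiles, "gender")
            hits += rec["significant"]
        rate = hits / n_rep
        assert 0.03 <= rate <= 0.075
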
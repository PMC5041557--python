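import itertools

import numpy as np
import pytest
from scipy import stats

from operat.instrument import load_instrument
from operat.psychometrics import (
    ResidentSurvey,
    aesthetic_attachment,
    convergent_validity,
    eligible_residents,
    item_domain_consistency,
    krippendorff_alpha,
    reliability_report,
    utility_anova,
    variance_explained,
)
from operat.scoring import score_area
from operat.synthetic import SimulationConfig, simulate_second_rater
from tests.conftest import make_assessment


def alpha_oracle(ratings, metric):
    """Independent brute-force alpha: explicit pair enumeration.

    Observed disagreement averages the squared difference over every ordered
    pair of ratings within each unit (weight 1/(m_u - 1)); expected
    disagreement averages over every ordered pair across all ratings.
    """
    rows = [r[~np.isnan(r)] for r in np.asarray(ratings, float)]
    rows = [r for r in rows if len(r) >= 2]
    pooled = np.concatenate(rows)
    values = np.sort(np.unique(pooled))
    n_c = np.array([(pooled == v).sum() for v in values], float)

    def delta2(a, b):
        if metric == "nominal":
            return 0.0 if a == b else 1.0
        if metric == "interval":
            return (a - b) ** 2
        ia, ib = np.searchsorted(values, [a, b])
        lo, hi = min(ia, ib), max(ia, ib)
        return (n_c[lo : hi + 1].sum() - (n_c[ia] + n_c[ib]) / 2.0) ** 2

    num = den = 0.0
    for row in rows:
        m = len(row)
        for a, b in itertools.permutations(range(m), 2):
            num += delta2(row[a], row[b]) / (m - 1)
    n = n_c.sum()
    for va, vb in itertools.product(pooled, repeat=2):
        den += delta2(va, vb)  # self-pairs contribute zero difference
    Do = num / n
    De = den / (n * (n - 1))
    return 1.0 - Do / De


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        X = np.array([[1, 1], [2, 2], [3, 3], [1, 1]], float)
        alpha, note = krippendorff_alpha(X, "nominal")
        assert alpha == pytest.approx(1.0)
        assert note is None

    def test_degenerate_identical_data(self):
        X = np.ones((4, 2))
        alpha, note = krippendorff_alpha(X, "nominal")
        assert alpha == 1.0
        assert "degenerate" in note

    @pytest.mark.parametrize("metric", ["nominal", "ordinal", "interval"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, metric, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 4, size=(6, 3)).astype(float)
        X[rng.random(X.shape) < 0.2] = np.nan  # missing entries allowed
        valid = [r for r in X if (~np.isnan(r)).sum() >= 2]
        if len(valid) < 2 or len(np.unique(np.concatenate(valid)[~np.isnan(np.concatenate(valid))])) < 2:
            pytest.skip("degenerate draw")
        alpha, _ = krippendorff_alpha(X, metric)
        assert alpha == pytest.approx(alpha_oracle(X, metric), abs=1e-10)

    def test_known_nominal_example(self):
        # two raters, binary codes: hand-computable coincidence matrix
        X = np.array([[0, 0], [1, 1], [0, 1], [0, 0], [1, 1]], float)
        alpha, _ = krippendorff_alpha(X, "nominal")
        assert alpha == pytest.approx(alpha_oracle(X, "nominal"), abs=1e-12)

    def test_random_rater_is_chance_level(self):
        rng = np.random.default_rng(1)
        alphas = []
        for _ in range(30):
            a = rng.integers(0, 4, 40).astype(float)
            b = rng.permutation(a)
            alphas.append(krippendorff_alpha(np.column_stack([a, b]), "nominal")[0])
        assert abs(float(np.mean(alphas))) < 0.05

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            krippendorff_alpha(np.array([[1.0, np.nan], [np.nan, 2.0]]))


class TestVarianceExplained:
    def test_strong_territorial_deprivation_association(self):
        assert variance_explained(0.67, "truncate") == 44

    def test_weak_association_rounds_to_five(self):
        assert variance_explained(0.22, "round") == 5

    def test_perfect_correlation(self):
        assert variance_explained(1.0, "round") == 100

    def test_sign_invariance(self):
        for r in (0.11, 0.3, 0.67):
            assert variance_explained(-r) == variance_explained(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(1.2)


class TestAestheticAttachment:
    def _survey(self, s1, s2, s3):
        return ResidentSurvey(
            "r", "A", 70.0, {}, {
                "scenery_importance": s1,
                "space_importance": s2,
                "peacefulness_importance": s3,
            },
        )

    def test_anchors_and_midpoint(self):
        assert aesthetic_attachment(self._survey(5, 5, 5)) == 100.0
        assert aesthetic_attachment(self._survey(1, 1, 1)) == 0.0
        assert aesthetic_attachment(self._survey(3, 3, 3)) == 50.0

    def test_missing_item_listwise_error(self):
        s = self._survey(5, 5, 5)
        s.attachment.pop("space_importance")
        with pytest.raises(ValueError, match="space_importance"):
            aesthetic_attachment(s)


class TestItemDomainConsistency:
    def test_structured_data_all_items_pass(self, spec, bundle):
        table = item_domain_consistency(bundle.assessments, spec)
        assert len(table) == 16
        assert table["passed"].all()
        assert (table["spearman"] > 0.2).all()

    def test_single_item_domain_correlates_perfectly(self):
        config = """
instrument_name: tiny
domains:
  - {domain_id: solo, name: Natural Elements, eag_weight: 1}
items:
  - {item_id: only, label: only, domain_id: solo, value_kind: proportion,
     desirable_direction: presence_bad, multiplier: 2}
"""
        tiny = load_instrument(config)
        from operat.instrument import AreaAssessment

        rng = np.random.default_rng(0)
        assessments = [
            AreaAssessment(f"A{i}", {"only": float(rng.uniform())}) for i in range(15)
        ]
        table = item_domain_consistency(assessments, tiny)
        assert table.loc[0, "spearman"] == 1.0

    def test_pure_noise_item_fails_mostly(self, spec, bundle):
        # replace one item's observations with noise; its correlation drops
        rng = np.random.default_rng(3)
        import copy

        assessments = copy.deepcopy(bundle.assessments[:200])
        for a in assessments:
            a.observations["litter_dog_fouling"] = float(rng.integers(0, 4))
        # the item-rest variant removes the noise item's own (large) share of
        # the total, exposing its lack of coherence with the domain
        table = item_domain_consistency(assessments, spec, item_rest=True)
        table = table.set_index("item_id")
        assert table.loc["litter_dog_fouling", "spearman"] < 0.2

    def test_constant_item_reported_not_raised(self, spec, bundle):
        import copy

        assessments = copy.deepcopy(bundle.assessments[:50])
        for a in assessments:
            a.observations["cars_passing"] = 1.0
        table = item_domain_consistency(assessments, spec).set_index("item_id")
        assert not table.loc["cars_passing", "passed"]
        assert table.loc["cars_passing", "reason"] == "constant"

    def test_too_few_areas_rejected(self, spec, bundle):
        with pytest.raises(ValueError):
            item_domain_consistency(bundle.assessments[:5], spec)


class TestConvergentValidity:
    def test_planted_coupling_signs_recovered(self, spec, bundle):
        reports = [score_area(spec, a) for a in bundle.assessments]
        residents = eligible_residents(
            bundle.resident_survey, {a.area_id for a in bundle.assessments}
        )
        dep = {
            a.area_id: a.covariates.deprivation_index for a in bundle.assessments
        }
        table = convergent_validity(reports, residents, dep)
        cell = table.set_index(["measure", "domain_id"])
        # safety at night couples positively to incivilities
        row = cell.loc[("safe_night", "incivilities_nuisance")]
        assert row["r_s"] > 0 and row["p"] < 0.05
        # deprivation row reproduces the configured sign pattern
        dep_rows = table[table["measure"] == "deprivation_index"].set_index("domain_id")
        signs = np.sign(dep_rows["r_s"][list(spec.domain_ids)].to_numpy())
        assert list(signs) == [1, 1, -1, 1]
        # territorial functioning carries the strong deprivation association
        assert dep_rows.loc["territorial_functioning", "r_s"] > 0.5

    def test_null_survey_mostly_nonsignificant(self, spec, bundle):
        rng = np.random.default_rng(8)
        reports = [score_area(spec, a) for a in bundle.assessments]
        noise = [
            ResidentSurvey(
                f"n{i}",
                bundle.assessments[int(rng.integers(405))].area_id,
                70.0,
                {p: int(rng.integers(1, 7)) for p in
                 ("enjoy_living", "desirable_place", "safe_day", "safe_night")},
                {p: int(rng.integers(1, 6)) for p in
                 ("scenery_importance", "space_importance", "peacefulness_importance")},
            )
            for i in range(400)
        ]
        table = convergent_validity(reports, noise)
        frac_sig = (table["p"] < 0.05).mean()
        assert frac_sig <= 0.25
        assert table["r_s"].abs().max() < 0.2

    def test_unlinked_respondents_rejected(self, spec, bundle):
        reports = [score_area(spec, a) for a in bundle.assessments[:5]]
        stranger = ResidentSurvey("s", "NOWHERE", 70.0, {}, {})
        with pytest.raises(ValueError):
            convergent_validity(reports, [stranger])


class TestUtilityAnova:
    def _toy_scores(self, groups_values):
        from operat.scoring import ScoreReport

        scores, groups = [], {}
        i = 0
        for g, values in groups_values.items():
            for v in values:
                aid = f"A{i}"
                scores.append(
                    ScoreReport(aid, {"d": v}, {"d": float(v)}, float(v))
                )
                groups[aid] = g
                i += 1
        return scores, groups

    def test_f_matches_hand_computed_sums_of_squares(self):
        data = {"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [5, 6, 7]}
        scores, groups = self._toy_scores(data)
        res = utility_anova(scores, groups, "toy")[0]
        # brute-force decomposition
        allv = np.concatenate([np.array(v, float) for v in data.values()])
        grand = allv.mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_w = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in data.values())
        F = (ss_b / 2) / (ss_w / 6)
        assert res.F == pytest.approx(F)
        assert (res.df_between, res.df_within) == (2, 6)
        # conservation: total SS = between + within
        assert ((allv - grand) ** 2).sum() == pytest.approx(ss_b + ss_w)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        scores, groups = self._toy_scores({"a": a, "b": b})
        res = utility_anova(scores, groups, "toy")[0]
        t, _ = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 2, 20)
        scores, groups = self._toy_scores(
            {"g1": base, "g2": rng.normal(10, 2, 20), "g3": rng.normal(10, 2, 20)}
        )
        res = utility_anova(scores, groups, "toy")[0]
        assert res.p > 0.01
        # all groups end up sharing one homogeneous subset
        assert any(len(s) == 3 for s in res.tukey_subsets)

    def test_shifted_group_isolated_in_tukey_subset(self):
        rng = np.random.default_rng(2)
        scores, groups = self._toy_scores(
            {
                "low1": rng.normal(10, 2, 15),
                "low2": rng.normal(10.2, 2, 15),
                "high": rng.normal(18, 2, 15),
            }
        )
        res = utility_anova(scores, groups, "toy")[0]
        assert res.p < 0.001
        assert ("high",) in res.tukey_subsets
        assert {"low1", "low2"} in [set(s) for s in res.tukey_subsets]

    def test_small_group_rejected(self):
        scores, groups = self._toy_scores({"a": [1, 2, 3], "b": [9]})
        with pytest.raises(ValueError):
            utility_anova(scores, groups, "toy")


class TestReliabilityReport:
    def test_duplicate_rater_gives_all_alpha_one(self, spec, bundle):
        subset = bundle.assessments[:10]
        results, perfect = reliability_report(subset, subset, spec)
        assert all(r.alpha == 1.0 for r in results)
        assert perfect == 16

    def test_five_percent_disagreement_passes_mostly(self, spec, bundle):
        pass_counts = []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, rater_disagreement_rate=0.05)
            rng = np.random.default_rng(seed)
            rater_b = simulate_second_rater(bundle.assessments[:10], cfg, spec, rng)
            results, _ = reliability_report(bundle.assessments[:10], rater_b, spec)
            pass_counts.append(sum(r.passed for r in results))
        assert np.mean(pass_counts) >= 12  # most of 16 items, most seeds

    def test_heavy_disagreement_fails_items(self, spec, bundle):
        cfg = SimulationConfig(seed=0, rater_disagreement_rate=0.5)
        rng = np.random.default_rng(0)
        rater_b = simulate_second_rater(bundle.assessments[:10], cfg, spec, rng)
        results, _ = reliability_report(bundle.assessments[:10], rater_b, spec)
        assert sum(not r.passed for r in results) >= 8

    def test_mismatched_area_sets_rejected(self, spec, bundle):
        with pytest.raises(ValueError, match="differ"):
            reliability_report(
                bundle.assessments[:10], bundle.assessments[5:15], spec
            )
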
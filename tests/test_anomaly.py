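import numpy as np
import pytest

from archform.anomaly import (
    CATEGORIES,
    AnomalyError,
    AnomalyFlags,
    classify_anomaly,
    detect_form_outlier,
    detect_mismatch,
    estimate_anomaly_probability,
    score_anomalies,
    summarize_proportions,
)
from archform.shape_stats import ArchClusterModel, build_association_matrix, cluster_arch_forms
from archform.synthetic_data import (
    SyntheticCohortConfig,
    default_dental_templates,
    generate_cohort,
    template_shape_vector,
)


def toy_model(mu=1.0, sigma=0.1, m=6):
    return ArchClusterModel(
        k=1,
        centers=np.zeros((1, m)),
        labels=np.ones(10, dtype=int),
        member_distances=np.full(10, mu),
        mu=np.array([mu]),
        sigma=np.array([sigma]),
    )


class TestOutlierRule:
    def test_two_sided_rule_flags_a_center_hit(self):
        # distance 0 < mu - 1.96 sigma: outside the printed range, so flagged
        model = toy_model(mu=1.0, sigma=0.1)
        out, cluster = detect_form_outlier(np.zeros(6), model)
        assert out and cluster == 1

    def test_one_sided_option_keeps_center_hit(self):
        model = toy_model(mu=1.0, sigma=0.1)
        out, _ = detect_form_outlier(np.zeros(6), model, two_sided=False)
        assert not out

    def test_form_at_mean_distance_not_flagged(self):
        model = toy_model(mu=1.0, sigma=0.1)
        form = np.zeros(6)
        form[0] = 1.0  # distance exactly mu
        out, _ = detect_form_outlier(form, model)
        assert not out

    def test_dimension_mismatch_raises(self):
        with pytest.raises(AnomalyError):
            detect_form_outlier(np.zeros(4), toy_model(m=6))

    def test_flag_rate_matches_analytic_five_percent(self):
        # distances drawn Normal(mu, sigma): P(|Z| > 1.96) = 0.05
        rng = np.random.default_rng(11)
        m, mu, sigma = 50, 1.0, 0.1

        def draws(n):
            d = rng.normal(mu, sigma, n)
            u = rng.normal(size=(n, m))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            return d[:, None] * u

        model = cluster_arch_forms(draws(4000), k=1, seed=0)
        flags = np.array([detect_form_outlier(f, model)[0] for f in draws(2000)])
        bound = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(flags.mean() - 0.05) < bound + 0.005


class TestMismatch:
    def setup_method(self):
        self.assoc = build_association_matrix([1, 1, 1, 2], [1, 1, 2, 2])

    def test_zero_cell_is_mismatch(self):
        assert detect_mismatch(2, 1, self.assoc, epsilon=0.01)

    def test_max_cell_is_not_mismatch(self):
        assert not detect_mismatch(1, 1, self.assoc, epsilon=0.5)

    def test_threshold_comparison(self):
        assoc = build_association_matrix([1] * 199 + [2], [1] * 199 + [2])
        assert detect_mismatch(2, 2, assoc, epsilon=0.01)  # cell 0.005 < 0.01
        assert not detect_mismatch(2, 2, assoc, epsilon=0.004)

    def test_invalid_ids_raise(self):
        with pytest.raises(Exception):
            detect_mismatch(9, 1, self.assoc, epsilon=0.01)


class TestCategories:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((False, False, False), "none"),
            ((True, False, False), "AD"),
            ((False, True, False), "AA"),
            ((False, False, True), "MDA"),
            ((True, True, False), "AD+AA"),
            ((True, False, True), "AD+MDA"),
            ((False, True, True), "AA+MDA"),
            ((True, True, True), "AD+AA+MDA"),
        ],
    )
    def test_all_eight_combinations(self, flags, expected):
        assert classify_anomaly(AnomalyFlags(*flags)) == expected
        assert expected in CATEGORIES


class TestMultiRound:
    def make_reference(self, n=209, seed=5):
        cfg = SyntheticCohortConfig(n_subjects=n, seed=seed)
        casts, _ = generate_cohort(cfg)
        return (
            np.array([c.dental_shape for c in casts]),
            np.array([c.alveolar_shape for c in casts]),
        )

    def test_threshold_validation(self):
        ref_d, ref_a = self.make_reference(n=60)
        with pytest.raises(AnomalyError):
            score_anomalies(ref_d[:1], ref_a[:1], ref_d, ref_a, rounds=5, threshold=9, k=2)

    def test_single_round_equals_direct_detection(self):
        ref_d, ref_a = self.make_reference(n=120, seed=8)
        form_d, form_a = ref_d[0], ref_a[0]
        report = estimate_anomaly_probability(
            form_d, form_a, (ref_d, ref_a), rounds=1, threshold=0, seed=3, k=6
        )
        model_d = cluster_arch_forms(ref_d, k=6, seed=int(np.random.SeedSequence(3).generate_state(1)[0] % 2**31))
        ad, _ = detect_form_outlier(form_d, model_d)
        assert report.flags.ad == ad
        assert report.detection_fraction["ad"] in (0.0, 1.0)

    def test_planted_outlier_always_detected(self):
        ref_d, ref_a = self.make_reference(seed=9)
        tpl = template_shape_vector(default_dental_templates()[2])
        rng = np.random.default_rng(0)
        u = rng.normal(size=50)
        u /= np.linalg.norm(u)
        outlier_d = tpl + 10 * 0.02 * np.sqrt(50) * u  # far outside every cluster
        report = estimate_anomaly_probability(
            outlier_d, ref_a[0], (ref_d, ref_a), rounds=10, threshold=5, seed=4, k=6
        )
        assert report.flags.ad
        assert report.detection_fraction["ad"] == 1.0

    def test_template_center_rarely_flagged(self):
        ref_d, ref_a = self.make_reference(seed=10)
        d = template_shape_vector(default_dental_templates()[2])
        from archform.synthetic_data import default_alveolar_templates

        a = template_shape_vector(default_alveolar_templates()[2])
        # an exact center hit is "too close" under the two-sided rule (the
        # distance falls below mu - 1.96 sigma), so the upper-tail rule is
        # the meaningful check for a perfectly typical form
        report = estimate_anomaly_probability(
            d, a, (ref_d, ref_a), rounds=10, seed=6, k=6, two_sided=False
        )
        assert report.detection_fraction["ad"] <= 0.1
        assert report.detection_fraction["aa"] <= 0.1

    def test_detection_monotone_in_magnitude(self):
        ref_d, ref_a = self.make_reference(n=120, seed=12)
        tpl = template_shape_vector(default_dental_templates()[1])
        rng = np.random.default_rng(1)
        u = rng.normal(size=50)
        u /= np.linalg.norm(u)
        fractions = []
        for mag in (0.0, 4.0, 8.0, 16.0):
            form = tpl + mag * 0.02 * u
            rep = estimate_anomaly_probability(
                form, ref_a[0], (ref_d, ref_a), rounds=5, seed=7, k=6
            )
            fractions.append(rep.detection_fraction["ad"])
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_mismatched_pairs_flagged(self):
        cfg = SyntheticCohortConfig(n_subjects=209, seed=13)
        normals, _ = generate_cohort(cfg)
        ref_d = np.array([c.dental_shape for c in normals])
        ref_a = np.array([c.alveolar_shape for c in normals])
        pcfg = SyntheticCohortConfig(n_subjects=40, mismatch_rate=0.25, seed=14)
        pats, truth = generate_cohort(pcfg)
        reports = score_anomalies(
            np.array([c.dental_shape for c in pats]),
            np.array([c.alveolar_shape for c in pats]),
            ref_d,
            ref_a,
            rounds=10,
            seed=2,
            k=6,
            jaw="mandible",
        )
        planted = [r.flags.mda for r, t in zip(reports, truth["mda"]) if t]
        assert np.mean(planted) >= 0.95


class TestProportions:
    def make_report(self, category, jaw="maxilla"):
        flags = AnomalyFlags(
            ad="AD" in category.split("+"),
            aa="AA" in category.split("+"),
            mda="MDA" in category.split("+"),
        )
        return type(
            "R", (), {"category": category, "jaw": jaw, "flags": flags}
        )()

    def test_hand_counted_proportions(self):
        cats = ["AD"] * 2 + ["MDA"] * 1 + ["none"] * 7
        out = summarize_proportions([self.make_report(c) for c in cats])
        p = out["maxilla"]["proportions"]
        assert np.isclose(p["AD"], 0.2) and np.isclose(p["MDA"], 0.1)
        assert np.isclose(out["maxilla"]["overall"], 0.3)

    def test_all_none(self):
        out = summarize_proportions([self.make_report("none")] * 5)
        assert out["maxilla"]["overall"] == 0.0

    def test_proportions_sum_to_one_per_jaw(self):
        rng = np.random.default_rng(3)
        reports = [
            self.make_report(CATEGORIES[rng.integers(len(CATEGORIES))], jaw=j)
            for j in ("maxilla", "mandible")
            for _ in range(25)
        ]
        out = summarize_proportions(reports)
        for jaw in ("maxilla", "mandible"):
            assert np.isclose(sum(out[jaw]["proportions"].values()), 1.0)

    def test_empty_raises(self):
        with pytest.raises(AnomalyError):
            summarize_proportions([])
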
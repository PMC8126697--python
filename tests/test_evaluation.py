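import dataclasses
import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalnet.errors import InfeasibleError, ValidationError
from ictalnet.evaluation import (
    EvalResult,
    auprc,
    inclusion_filter,
    kruskal_wallis_by_site,
    lopo_evaluate,
    onset_mae,
    select_seed,
    tolerance_accuracy,
)
from ictalnet.io import RecordingMetadata, load_cohort_table
from ictalnet.network import NetworkSpec
from ictalnet.synthetic import CohortConfig, generate_cohort
from ictalnet.training import TrainConfig
from ictalnet.augment import AugmentConfig


def auprc_oracle(labels, scores):
    """Exhaustive threshold enumeration, independent of the implementation."""
    labels = list(labels)
    scores = list(scores)
    n_pos = sum(labels)
    points = []  # (recall, precision) per distinct threshold, descending
    for tau in sorted(set(scores), reverse=True):
        tp = sum(1 for y, s in zip(labels, scores) if s >= tau and y == 1)
        fp = sum(1 for y, s in zip(labels, scores) if s >= tau and y == 0)
        points.append((tp / n_pos, tp / (tp + fp)))
    area = 0.0
    prev_recall = 0.0
    for recall, precision in points:
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestAUPRC:
    def test_perfect_separation(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)

    def test_frozen_example(self):
        # oracle value: thresholds .9/.8/.7/.1 -> AP = 0.5*1 + 0.5*(2/3) = 5/6
        got = auprc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert got == pytest.approx(5.0 / 6.0)
        assert got == pytest.approx(auprc_oracle([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]))

    def test_reversed_perfect_ranking_matches_oracle(self):
        labels = [1, 1, 0, 0, 0, 0]
        scores = [0.1, 0.2, 0.7, 0.8, 0.9, 0.95]
        assert auprc(labels, scores) == pytest.approx(auprc_oracle(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auprc([1, 1], [0.5, 0.6])
        with pytest.raises(ValidationError):
            auprc([0, 0], [0.5, 0.6])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_on_small_instances(self, data):
        n = data.draw(st.integers(2, 12))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        # few distinct score values to force ties
        scores = data.draw(
            st.lists(st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9]), min_size=n, max_size=n)
        )
        assert auprc(labels, scores) == pytest.approx(auprc_oracle(labels, scores))

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=n), 2)
            assert auprc(labels, scores) == pytest.approx(
                average_precision_score(labels, scores)
            )


class TestRegressionMetrics:
    def test_exact_predictions(self):
        anns = [10.0, 20.0, 30.0]
        assert onset_mae(anns, anns) == 0.0
        assert tolerance_accuracy(anns, anns) == 1.0

    def test_mae_arithmetic(self):
        assert onset_mae([10.0, 20.0], [12.0, 16.0]) == pytest.approx(3.0)

    def test_mae_bounded_by_max_error(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 20))
            t = rng.uniform(0, 90, size=n)
            th = rng.uniform(-10, 100, size=n)
            assert onset_mae(t, th) <= np.abs(th - t).max() + 1e-12

    def test_tolerance_strict_inequality(self):
        t = [10.0, 10.0, 10.0]
        th = [14.9, 15.0, 15.1]
        assert tolerance_accuracy(t, th, tol=5.0) == pytest.approx(1 / 3)

    def test_tolerance_zero(self):
        assert tolerance_accuracy([1.0, 2.0], [1.0, 2.5], tol=0.0) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            onset_mae([], [])

    def test_nonictal_annotation_rejected(self):
        from ictalnet.io import OnsetAnnotation

        with pytest.raises(ValidationError):
            onset_mae([OnsetAnnotation(s=0)], [5.0])


class TestKruskalWallis:
    def _results(self, groups):
        out = []
        site_map = {}
        i = 0
        for site, values in groups.items():
            for v in values:
                pid = f"p{i}"
                out.append(EvalResult(pid, 10, v, 1.0, 0.5, 10))
                site_map[pid] = site
                i += 1
        return out, site_map

    def test_identical_groups_h_zero(self):
        results, sites = self._results({"a": [0.5, 0.5], "b": [0.5, 0.5]})
        h, p = kruskal_wallis_by_site(results, sites)
        assert h == 0.0

    def test_hand_computed_h(self):
        # ranks 1..6, rank sums 6 and 15 -> H = 12/42*(12+75) - 21 = 27/7
        results, sites = self._results({"a": [0.1, 0.2, 0.3], "b": [0.4, 0.5, 0.6]})
        h, p = kruskal_wallis_by_site(results, sites)
        assert h == pytest.approx(27.0 / 7.0)

    def test_chi2_p_close_to_permutation_oracle(self, rng):
        a = list(rng.uniform(0.3, 0.9, size=8))
        b = list(rng.uniform(0.4, 1.0, size=8))
        results, sites = self._results({"a": a, "b": b})
        h_obs, p_chi2 = kruskal_wallis_by_site(results, sites)
        pooled = np.array(a + b)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            res_p, sites_p = self._results({"a": list(perm[:8]), "b": list(perm[8:])})
            h_p, _ = kruskal_wallis_by_site(res_p, sites_p)
            if h_p >= h_obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3
        # chi2 approximation within Monte-Carlo error (generous band)
        assert abs(p_chi2 - p_perm) < max(5 * se, 0.06)

    def test_single_group_rejected(self):
        results, sites = self._results({"a": [0.1, 0.2]})
        with pytest.raises(ValidationError):
            kruskal_wallis_by_site(results, sites)


def _meta(pid, n_ictal, site="neocortex"):
    return RecordingMetadata(
        patient_id=pid,
        implant_site=site,
        n_days_with_device=100,
        n_ieeg_files=max(n_ictal, 100),
        n_ictal_patterns=n_ictal,
        age=30.0,
        sex="F",
    )


class TestInclusionFilter:
    def test_table1_yields_12_patients(self):
        assert len(inclusion_filter(load_cohort_table(), max_seed=30)) == 12

    def test_strict_threshold(self):
        records = [_meta("a", 35), _meta("b", 36)]
        assert inclusion_filter(records, max_seed=30) == ["b"]

    def test_max_seed_zero(self):
        records = [_meta("a", 5), _meta("b", 6)]
        assert inclusion_filter(records, max_seed=0) == ["b"]


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = CohortConfig(
        n_patients=3,
        epochs_per_patient=12,
        ictal_fraction=0.67,
        scheduled_fraction=1.0,
        master_seed=5,
    )
    return generate_cohort(cfg)


class TestSelectSeed:
    def test_earliest_consecutive_uses_chronology(self, tiny_cohort):
        pdata = tiny_cohort.patients[0]
        seed = select_seed(pdata, 2, "earliest_consecutive", np.random.default_rng(0))
        ictal = [
            (i, e.recorded_at)
            for i, (e, a) in enumerate(pdata.epochs)
            if a.s == 1
        ]
        expected = [i for i, _ in sorted(ictal, key=lambda x: x[1])[:2]]
        assert list(seed.ictal_ids) == sorted(expected)

    def test_seed_zero_is_empty(self, tiny_cohort):
        seed = select_seed(
            tiny_cohort.patients[0], 0, "random", np.random.default_rng(0)
        )
        assert seed.ictal_ids == () and seed.nonictal_ids == ()

    def test_random_scenario_deterministic(self, tiny_cohort):
        s1 = select_seed(tiny_cohort.patients[1], 3, "random", np.random.default_rng(9))
        s2 = select_seed(tiny_cohort.patients[1], 3, "random", np.random.default_rng(9))
        assert s1 == s2

    def test_pairing_is_scheduled_nonictal(self, tiny_cohort):
        pdata = tiny_cohort.patients[2]
        seed = select_seed(pdata, 2, "random", np.random.default_rng(4))
        for i in seed.nonictal_ids:
            epoch, ann = pdata.epochs[i]
            assert ann.s == 0 and epoch.trigger == "scheduled"

    def test_infeasible_names_shortfall(self, tiny_cohort):
        with pytest.raises(InfeasibleError, match="ictal"):
            select_seed(
                tiny_cohort.patients[0], 50, "random", np.random.default_rng(0)
            )


class TestLopo:
    SPEC = NetworkSpec(
        n_blocks=3,
        first_filters=4,
        penultimate_filters=4,
        per_block_filters=(4, 4, 4),
        n_patients=1,
        dropout_rate=0.0,
    )

    @pytest.fixture(scope="class")
    def outcome(self, tiny_cohort):
        return lopo_evaluate(
            tiny_cohort,
            scenario="random",
            seed_sizes=(0, 2),
            train_config=TrainConfig(n_epochs=1, batch_size=16, seed=0),
            rng=np.random.default_rng(3),
            network_spec=self.SPEC,
            augment_config=AugmentConfig(enabled=False),
        )

    def test_row_count(self, tiny_cohort, outcome):
        qualifying = inclusion_filter(tiny_cohort.metadata(), max_seed=2)
        expected = len(qualifying) * 2 - len(outcome.missing)
        assert len(outcome.results) == expected
        assert len(outcome.results) > 0

    def test_test_epoch_counts_exclude_seed(self, tiny_cohort, outcome):
        for r in outcome.results:
            n_total = next(
                len(p.epochs)
                for p in tiny_cohort.patients
                if p.profile.patient_id == r.patient_id
            )
            assert r.n_test_epochs == n_total - 2 * r.seed_size

    def test_summary_covers_seed_sizes(self, outcome):
        assert set(outcome.summary) <= {0, 2}
        for row in outcome.summary.values():
            assert 0.0 <= row["auprc_mean"] <= 1.0
            lo, hi = row["auprc_ci95"]
            assert lo <= row["auprc_mean"] <= hi

    def test_requires_two_patients(self, tiny_cohort):
        from ictalnet.synthetic import Cohort

        single = Cohort(config=tiny_cohort.config, patients=tiny_cohort.patients[:1])
        with pytest.raises(ValidationError):
            lopo_evaluate(single)
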
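"""Group tests, FDR adjustment and behaviour-correlation screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from ratconnectome.stats import (
    SubjectRecord,
    fdr_adjust,
    glm_group_age,
    group_metric_tests,
    kruskal_wallis,
    read_subjects,
    spearman_screen,
    write_subjects,
)

from oracles import kw_h_oracle, spearman_oracle


def make_subjects(n_per_group, ages_control=None, ages_tg=None, rng=None):
    rng = rng or np.random.default_rng(0)
    ages_control = ages_control if ages_control is not None else rng.normal(151, 12, n_per_group)
    ages_tg = ages_tg if ages_tg is not None else rng.normal(181, 32, n_per_group)
    subs = [
        SubjectRecord(f"c{i}", "control", float(max(a, 40)))
        for i, a in enumerate(ages_control)
    ]
    subs += [
        SubjectRecord(f"t{i}", "transgenic", float(max(a, 40)))
        for i, a in enumerate(ages_tg)
    ]
    return subs


class TestKruskalWallis:
    def test_no_separation_full_ties(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fully_separated_hand_value(self):
        # ranks 1..3 vs 4..6: H = (12/42)*(36/3 + 225/3) - 21 = 27/7
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(27 / 7)
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_identical_constant_samples(self):
        assert kruskal_wallis([5, 5], [5, 5]) == (0.0, 1.0)

    def test_matches_scipy_and_rank_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 1, rng.integers(3, 10))
            h, p = kruskal_wallis(a, b)
            h_scipy, p_scipy = sp_stats.kruskal(a, b)
            assert h == pytest.approx(h_scipy, abs=1e-10)
            assert p == pytest.approx(p_scipy, abs=1e-10)
            assert h == pytest.approx(kw_h_oracle(a, b), abs=1e-10)

    def test_exact_permutation_close_to_chi2_reference(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(1.0, 1, 6)
        h, p_exact = kruskal_wallis(a, b, exact=True)
        _, p_chi2 = kruskal_wallis(a, b)
        assert 0 <= p_exact <= 1
        # chi-square is an approximation; they should be in the same regime
        assert abs(p_exact - p_chi2) < 0.12

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.uniform(1, 5, 7)
        b = rng.uniform(2, 6, 7)
        h1, _ = kruskal_wallis(a, b)
        h2, _ = kruskal_wallis(np.exp(a), np.exp(b))
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1], [2, 3])


class TestGLM:
    def test_equal_ages_reduces_to_t_test(self, rng):
        subs = make_subjects(6, ages_control=[150] * 6, ages_tg=[150] * 6)
        values = rng.normal(0, 1, 12)
        values[6:] += 1.0
        effect, p = glm_group_age(values, subs)
        t_res = sp_stats.ttest_ind(values[6:], values[:6], equal_var=True)
        assert p == pytest.approx(t_res.pvalue, abs=1e-10)
        assert effect == pytest.approx(values[6:].mean() - values[:6].mean(), abs=1e-10)

    def test_age_coefficient_recovery(self, rng):
        subs = make_subjects(20, rng=rng)
        ages = np.array([s.age_days for s in subs])
        values = 2.0 * ages + rng.normal(0, 0.5, len(subs))
        effect, p = glm_group_age(values, subs)
        # zero group effect: the group coefficient stays near zero
        assert abs(effect) < 1.0

    def test_group_confounded_with_age_rejected(self):
        subs = make_subjects(4, ages_control=[100] * 4, ages_tg=[200] * 4)
        with pytest.raises(ValueError, match="collinear"):
            glm_group_age(np.arange(8.0), subs)

    def test_null_type_one_error_controlled(self):
        """Age confounded with group (as in the cohort design) must not
        inflate the GLM's group-test false-positive rate."""
        rng = np.random.default_rng(123)
        n_sim, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_sim):
            subs = make_subjects(9, rng=rng)
            ages = np.array([s.age_days for s in subs])
            # metric depends on age but NOT on group
            values = 0.01 * ages + rng.normal(0, 0.5, 18)
            _, p = glm_group_age(values, subs)
            rejections += p < alpha
        rate = rejections / n_sim
        assert 0.02 <= rate <= 0.08


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_case(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_never_decreases_and_order_preserved(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        # sorted order of adjusted values follows sorted raw order (step-up monotone)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_passing_set_shrinks(self, rng):
        p = rng.uniform(0, 0.2, 20)
        adj = fdr_adjust(p)
        assert set(np.flatnonzero(adj <= 0.05)) <= set(np.flatnonzero(p <= 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


def tidy_metrics(values_by_subject, metric="m", kind="fa_weighted", scope="global"):
    rows = []
    for sid, v in values_by_subject.items():
        rows.append(
            {
                "subject_id": sid,
                "connectome_kind": kind,
                "scope": scope,
                "node_label": "" if scope == "global" else "R1 (right)",
                "metric_name": metric,
                "value": v,
            }
        )
    return pd.DataFrame(rows)


class TestSpearmanScreen:
    def _behavior(self, values):
        return pd.DataFrame(
            {"subject_id": list(values.keys()), "sessions": list(values.values())}
        )

    def test_perfect_monotone_flagged(self):
        metrics = tidy_metrics({f"s{i}": i for i in range(6)})
        up = self._behavior({f"s{i}": i**2 for i in range(6)})
        rows = spearman_screen(metrics, up)
        assert rows.iloc[0]["spearman_r"] == pytest.approx(1.0)
        assert bool(rows.iloc[0]["flagged"])
        down = self._behavior({f"s{i}": -3 * i for i in range(6)})
        rows = spearman_screen(metrics, down)
        assert rows.iloc[0]["spearman_r"] == pytest.approx(-1.0)
        assert bool(rows.iloc[0]["flagged"])

    def test_matches_rank_pearson_oracle(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0, 1, 6)
        metrics = tidy_metrics({f"s{i}": x[i] for i in range(6)})
        rows = spearman_screen(metrics, self._behavior({f"s{i}": y[i] for i in range(6)}))
        assert rows.iloc[0]["spearman_r"] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_flag_strictly_above_threshold(self):
        metrics = tidy_metrics({f"s{i}": v for i, v in enumerate([1, 2, 3, 4, 5])})
        behavior = self._behavior({f"s{i}": v for i, v in enumerate([1, 2, 3, 5, 4])})
        rows = spearman_screen(metrics, behavior, threshold=0.9)
        assert rows.iloc[0]["spearman_r"] == pytest.approx(0.9)
        assert not bool(rows.iloc[0]["flagged"])  # 0.9 is not > 0.9

    def test_constant_vector_skipped(self, caplog):
        metrics = tidy_metrics({f"s{i}": 1.0 for i in range(5)})
        rows = spearman_screen(metrics, self._behavior({f"s{i}": i for i in range(5)}))
        assert rows.empty

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        m1 = tidy_metrics({f"s{i}": x[i] for i in range(10)})
        m2 = tidy_metrics({f"s{i}": np.exp(x[i]) for i in range(10)})
        b = self._behavior({f"s{i}": y[i] for i in range(10)})
        r1 = spearman_screen(m1, b).iloc[0]["spearman_r"]
        r2 = spearman_screen(m2, b).iloc[0]["spearman_r"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestGroupMetricTests:
    def test_report_structure_and_fdr(self, rng):
        subs = make_subjects(5, rng=rng)
        frames = []
        for region in [f"R{k}" for k in range(6)]:
            rows = tidy_metrics(
                {s.subject_id: float(rng.normal()) for s in subs},
                metric="strength",
                scope="node",
            )
            rows["node_label"] = region
            frames.append(rows)
        metrics = pd.concat(frames, ignore_index=True)
        report = group_metric_tests(metrics, subs)
        assert set(report["test"]) == {"kruskal_wallis", "glm_group_age"}
        regional = report[report["scope"] == "node"]
        assert (regional["p_fdr"] >= regional["p_raw"] - 1e-15).all()
        assert regional["p_fdr"].between(0, 1).all()

    def test_unknown_subject_rejected(self, rng):
        subs = make_subjects(3, rng=rng)
        metrics = tidy_metrics({"nobody": 1.0, subs[0].subject_id: 2.0})
        with pytest.raises(ValueError, match="metadata"):
            group_metric_tests(metrics, subs)


class TestSubjectIO:
    def test_round_trip(self, tmp_path):
        subs = [
            SubjectRecord("a", "control", 150.0, {"training_sessions_total": 40.0}),
            SubjectRecord("b", "transgenic", 190.0, {"training_sessions_total": 65.0}),
        ]
        path = tmp_path / "subjects.csv"
        write_subjects(path, subs)
        back = read_subjects(path)
        assert [s.subject_id for s in back] == ["a", "b"]
        assert back[1].behavior["training_sessions_total"] == 65.0

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            SubjectRecord("x", "mutant", 100.0)
        with pytest.raises(ValueError):
            SubjectRecord("x", "control", -5.0)
        with pytest.raises(ValueError):
            SubjectRecord("x", "control", 100.0, {"pct_correct_total": 150.0})
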
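"""Separability screen: linear-rule oracle, permutation calibration,
categorization, pooling, stability, and the exact group test."""

import shutil
import subprocess

import numpy as np
import pytest
from scipy.stats import fisher_exact, kstest

from angerppg.separability import (
    SeparabilityConfig,
    categorize_participant,
    cosine_similarity_binary,
    group_distribution_test,
    linear1d_accuracy,
    permutation_null,
    pool_top_features,
    screen_session,
    significance,
    stability_matrix,
)


def _brute_force_accuracy(values, labels):
    """Exhaustive scan over all threshold/direction rules."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(values)
    thresholds = np.r_[uniq[0] - 1.0, (uniq[:-1] + uniq[1:]) / 2.0, uniq[-1] + 1.0]
    best = 0
    for thr in thresholds:
        pred = (values <= thr).astype(int)
        agree = int(np.sum(pred == labels))
        best = max(best, agree, len(labels) - agree)
    return best / len(labels)


class TestLinearRule:
    def test_perfectly_separated_classes(self):
        assert linear1d_accuracy(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_interleaved_example(self):
        assert linear1d_accuracy(np.array([1, 2, 3, 4.0]), np.array([1, 0, 1, 0])) == 0.75

    def test_constant_feature_scores_majority(self):
        vals = np.full(10, 3.14)
        labels = np.r_[np.ones(3, int), np.zeros(7, int)]
        assert linear1d_accuracy(vals, labels) == 0.7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            linear1d_accuracy(np.arange(5.0), np.ones(5, int))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            values = rng.choice([0.0, 0.5, 1.0, 2.0, 7.0], size=n) + rng.standard_normal(n) * rng.choice([0, 1])
            labels = rng.integers(0, 2, size=n)
            if labels.sum() < 2 or labels.sum() > n - 2:
                continue
            assert linear1d_accuracy(values, labels) == pytest.approx(
                _brute_force_accuracy(values, labels)
            )


class TestPermutationNull:
    def test_zero_exceedances_gives_min_p(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.ones(25, int), np.zeros(35, int)]
        values = labels * 10.0 + rng.standard_normal(60) * 0.01
        _, p = permutation_null(values, labels, k_perm=1000, seed=1)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_fixed_seed_reproduces_p_values(self, rng):
        values = rng.standard_normal(40)
        labels = rng.integers(0, 2, 40)
        labels[:2], labels[-2:] = 1, 0
        _, p1 = permutation_null(values, labels, k_perm=300, seed=7)
        _, p2 = permutation_null(values, labels, k_perm=300, seed=7)
        assert p1 == p2

    def test_permutation_preserves_label_multiset(self, rng):
        # the majority baseline is invariant under label permutation
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        perms = rng.permuted(np.tile(labels, (50, 1)), axis=1)
        assert (perms.sum(axis=1) == 10).all()

    def test_null_p_values_are_calibrated(self, rng):
        # labels independent of values: the smoothed (randomized) p computed
        # from the returned null sample is uniform; the reported p itself is
        # valid, i.e. super-uniform: P(p <= t) <= t + Monte-Carlo error
        n, k = 40, 500
        labels = np.r_[np.ones(14, int), np.zeros(26, int)]
        smoothed = []
        raw_p = []
        for i in range(400):
            values = rng.standard_normal(n)
            lab = rng.permutation(labels)
            null, p = permutation_null(values, lab, k_perm=k, seed=1000 + i)
            obs = linear1d_accuracy(values, lab)
            greater = int(np.sum(null > obs + 1e-12))
            ties = int(np.sum(np.abs(null - obs) <= 1e-12))
            smoothed.append((greater + rng.random() * (ties + 1)) / (k + 1))
            raw_p.append(p)
        assert kstest(smoothed, "uniform").pvalue > 0.01
        raw_p = np.asarray(raw_p)
        for t in (0.05, 0.1, 0.25, 0.5):
            emp = np.mean(raw_p <= t)
            mc = 3 * np.sqrt(t * (1 - t) / len(raw_p))
            assert emp <= t + mc


class TestSignificance:
    def test_all_p_one_yields_nothing(self):
        flags = significance(np.ones(20), np.full(20, 0.9), 0.6)
        assert not flags.any()

    def test_accuracy_at_baseline_never_significant(self):
        flags = significance(np.array([1e-6]), np.array([0.7]), 0.7)
        assert not flags.any()

    def test_null_sessions_control_false_discoveries(self, rng):
        # pure-null sessions: expected significant count <= q * bank size
        n_feat, n_win, k = 150, 40, 200
        labels = np.r_[np.ones(12, int), np.zeros(28, int)]
        counts = []
        for s in range(12):
            values = rng.standard_normal((n_win, n_feat))
            rep = screen_session(
                f"null-{s}", values, rng.permutation(labels),
                [f"F{j}.x" for j in range(n_feat)],
                SeparabilityConfig(k_perm=k, seed=s),
            )
            counts.append(rep.n_significant)
        mean = np.mean(counts)
        bound = 0.01 * n_feat
        se = np.std(counts) / np.sqrt(len(counts)) + 1e-9
        assert mean <= bound + 3 * se


class TestCategorization:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(45, 52, "strong"), (45, 12, "moderate"), (12, 45, "moderate"), (0, 0, "weak"), (40, 40, "strong")],
    )
    def test_rule(self, a, b, expected):
        assert categorize_participant(a, b, 40) == expected


def _report(sid, fams, n_sig=50):
    from angerppg.separability import SeparabilityReport

    ids = [f"{f}.out{i}" for i, f in enumerate(fams)]
    return SeparabilityReport(
        session_id=sid,
        feature_ids=ids,
        accuracies=np.linspace(0.99, 0.9, len(ids)),
        p_values=np.full(len(ids), 1e-3),
        significant=np.ones(len(ids), bool),
        majority_baseline=0.6,
        n_anger=10,
        n_windows=30,
    )


class TestPoolingAndStability:
    def test_family_tally_counts_sessions_not_occurrences(self):
        rep = _report("P01-A", ["MF_GARCH_ar_P1_Q2"] * 5)
        tally = pool_top_features([rep])
        assert tally == {"MF_GARCH_ar_P1_Q2": 1}

    def test_tally_bounded_by_session_count(self):
        reps = [_report(f"P0{i}-A", ["SP_Summaries_fft", "WL_fBM"]) for i in range(4)]
        tally = pool_top_features(reps)
        assert max(tally.values()) <= 4
        assert tally["SP_Summaries_fft"] == 4

    def test_cosine_contract(self):
        a = {f"f{i}" for i in range(40)}
        b = {f"f{i}" for i in range(20, 60)}  # 20-of-40 overlap
        assert cosine_similarity_binary(a, a) == 1.0
        assert cosine_similarity_binary(a, {f"g{i}" for i in range(40)}) == 0.0
        assert cosine_similarity_binary(a, b) == pytest.approx(0.5)

    def test_stability_matrix_properties(self):
        reps = [
            _report("P01-A", ["A", "B", "C"]),
            _report("P01-B", ["A", "B", "D"]),
            _report("P02-A", ["X", "Y", "Z"]),
        ]
        res = stability_matrix(reps, SeparabilityConfig())
        assert np.allclose(res.cosine, res.cosine.T)
        assert np.allclose(np.diag(res.cosine), 1.0)
        assert ((res.cosine >= 0) & (res.cosine <= 1)).all()
        # P01's two sessions share 2/3 families -> grouped; P02 isolated
        assert {"P01-A", "P01-B"} in res.groups

    def test_empty_top_list_scores_zero(self):
        from angerppg.separability import SeparabilityReport

        empty = SeparabilityReport(
            session_id="P09-A", feature_ids=["A.x"], accuracies=np.array([0.5]),
            p_values=np.array([1.0]), significant=np.zeros(1, bool),
            majority_baseline=0.6, n_anger=5, n_windows=20,
        )
        res = stability_matrix([empty, _report("P01-A", ["A", "B"])], SeparabilityConfig())
        assert res.cosine[0, 1] == 0.0
        assert "P09-A" in res.empty_sessions


class TestGroupDistributionTest:
    def test_published_category_table(self):
        assert group_distribution_test([[13, 7, 2], [5, 4, 1]]) == pytest.approx(
            0.858, abs=5e-4
        )

    def test_two_by_two_agrees_with_classical_fisher(self):
        mine = group_distribution_test([[8, 2], [1, 5]])
        assert mine == pytest.approx(fisher_exact([[8, 2], [1, 5]])[1], rel=1e-9)

    def test_probability_bound(self):
        assert group_distribution_test([[4, 4, 4], [2, 2, 2]]) <= 1.0

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert group_distribution_test([[0, 0, 0], [1, 2, 3]]) == 1.0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    @pytest.mark.parametrize(
        "table", [[[13, 7, 2], [5, 4, 1]], [[6, 1, 3], [2, 5, 0]], [[9, 9], [2, 7]]]
    )
    def test_agrees_with_r_fisher_test(self, table):
        rows = ",".join(str(v) for row in table for v in row)
        ncol = len(table[0])
        script = (
            f"m <- matrix(c({rows}), nrow=2, byrow=TRUE); "
            f"cat(fisher.test(m)$p.value)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        assert group_distribution_test(table) == pytest.approx(
            float(out.stdout.strip()), rel=1e-6
        )


class TestScreenOnGeneratedCohort:
    def test_strong_separability_with_default_anger_effect(self, small_pipeline):
        from angerppg.separability import screen_cohort

        reports = screen_cohort(
            small_pipeline.matrix, SeparabilityConfig(k_perm=200, seed=3)
        )
        by_pid = {}
        for r in reports:
            by_pid.setdefault(r.session_id.rsplit("-", 1)[0], []).append(r.n_significant)
        for pid, (a, b) in by_pid.items():
            assert categorize_participant(a, b) == "strong", (pid, a, b)
        for r in reports:
            # significant implies beating the majority baseline, strictly
            assert (r.accuracies[r.significant] > r.majority_baseline).all()
            assert ((r.p_values > 0) & (r.p_values <= 1)).all()
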
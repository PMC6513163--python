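"""AUPR, bootstrap pairing, Wilcoxon, F1-max, binding labels, baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from regionfp import evaluation as ev
from regionfp.evaluation import (
    BindingLabel,
    EvalResult,
    LigandClass,
    ResidueContactRecord,
    aupr,
    bootstrap_aupr,
    bootstrap_indices,
    compare_methods,
    f1max_threshold,
    identity_baseline,
    label_binding_regions,
    pairwise_identity,
    read_contact_tsv,
    wilcoxon_signed_rank,
    write_contact_tsv,
)
from regionfp.io_formats import ProteinSequence
from regionfp.region_builder import OriginType, Region, RegionSet


def brute_force_average_precision(scores, labels):
    """Independent PR-curve oracle for distinct scores: sum over positives,
    in decreasing-score order, of precision at each recall step."""
    order = np.argsort(scores)[::-1]
    labels = np.asarray(labels)[order]
    ap, tp = 0.0, 0
    for rank, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            ap += tp / rank
    return ap / labels.sum()


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_positive_ranked_last(self):
        assert aupr([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1]) == pytest.approx(0.25)

    def test_all_scores_equal_gives_prevalence(self):
        assert aupr([0.5] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]) == \
            pytest.approx(0.2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            aupr([0.1, 0.9], [1, 1])

    def test_matches_enumeration_oracle(self):
        # every labeling of up to 8 items with distinct scores
        for n in range(2, 9):
            scores = np.linspace(0.1, 0.9, n)
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    assert aupr(scores, labels) == pytest.approx(
                        brute_force_average_precision(scores, labels)
                    )

    @given(st.integers(min_value=0, max_value=2**16))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(12)
        labels = rng.integers(0, 2, size=12)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        transformed = np.exp(3 * scores) + 7
        assert aupr(scores, labels) == pytest.approx(aupr(transformed, labels))


class TestBootstrap:
    SCORES = np.array([0.9, 0.8, 0.7, 0.4, 0.3, 0.2, 0.6, 0.5])
    LABELS = np.array([1, 1, 0, 0, 1, 0, 0, 0])

    def test_bit_for_bit_reproducible(self):
        a = bootstrap_aupr(self.SCORES, self.LABELS, n_boot=50, seed=3)
        b = bootstrap_aupr(self.SCORES, self.LABELS, n_boot=50, seed=3)
        assert np.array_equal(a.bootstrap_auprs, b.bootstrap_auprs)

    def test_single_round_equals_point_aupr_on_resample(self):
        idx = bootstrap_indices(self.LABELS, 1, seed=5)
        res = bootstrap_aupr(self.SCORES, self.LABELS, n_boot=1, seed=5)
        assert res.bootstrap_auprs[0] == pytest.approx(
            aupr(self.SCORES[idx[0]], self.LABELS[idx[0]])
        )

    def test_methods_share_resample_indices(self):
        other = 1.0 - self.SCORES  # a different method, same items
        i1 = bootstrap_indices(self.LABELS, 20, seed=7)
        i2 = bootstrap_indices(self.LABELS, 20, seed=7)
        assert np.array_equal(i1, i2)  # depends on labels + seed only
        res = bootstrap_aupr(other, self.LABELS, n_boot=20, seed=7)
        assert res.bootstrap_auprs.shape == (20,)

    def test_resamples_never_single_class(self):
        labels = np.array([1] + [0] * 9)  # single-class draws are likely
        idx = bootstrap_indices(labels, 200, seed=0)
        for row in idx:
            assert labels[row].min() != labels[row].max()

    def test_bootstrap_mean_approaches_point_aupr(self):
        rng = np.random.default_rng(11)
        scores = rng.random(200)
        labels = (scores + rng.normal(scale=0.3, size=200) > 0.5).astype(int)
        res = bootstrap_aupr(scores, labels, n_boot=2000, seed=1)
        se = res.bootstrap_auprs.std() / np.sqrt(2000)
        # the bootstrap mean estimates the point AUPR up to O(1/n) bias
        assert abs(res.bootstrap_auprs.mean() - res.point_aupr) < \
            3 * se + 0.01


class TestWilcoxon:
    def test_identical_vectors(self):
        x = np.linspace(0, 1, 20)
        assert wilcoxon_signed_rank(x, x) == 1.0

    def test_constant_shift_saturates(self):
        rng = np.random.default_rng(0)
        b = rng.random(50)
        assert wilcoxon_signed_rank(b + 0.2, b) < 1e-6

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=12)
        while np.unique(np.abs(d)).size < 12 or np.any(d == 0):
            d = rng.normal(size=12)
        b = rng.random(12)
        p = wilcoxon_signed_rank(b + d, b)
        # enumerate all 2^12 sign assignments of |d| under the null
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=12)
        ]
        stats = np.array(stats)
        extreme = min(w_obs, total - w_obs)
        # both tails at once: assignments with W at least as extreme
        p_exact = np.mean(np.minimum(stats, total - stats) <= extreme)
        assert p == pytest.approx(min(p_exact, 1.0), rel=1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [2, 1])


class TestF1Max:
    def test_perfectly_separated(self):
        t, f1 = f1max_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert f1 == 1.0 and 0.2 < t <= 0.8

    def test_all_positive_labels(self):
        t, f1 = f1max_threshold([0.5, 0.3, 0.9], [1, 1, 1])
        assert (t, f1) == (0.3, 1.0)  # min score, everything called

    def test_brute_force_three_scores(self):
        scores, labels = [0.9, 0.8, 0.1], [1, 0, 0]
        t, f1 = f1max_threshold(scores, labels)
        # thresholds 0.1 -> F1 = 2*(1/3)*1/(1/3+1) = 0.5; 0.8 -> 2/3; 0.9 -> 1
        assert (t, f1) == (0.9, 1.0)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            f1max_threshold([0.1], [0])


class TestBindingLabels:
    def _region_set(self, length=100):
        p = ProteinSequence("P1", "A" * length)
        return RegionSet(p, [Region("P1", 1, 1, length, OriginType.DOMAIN)])

    def _contacts(self, n_close, length=100, covered_until=None):
        covered_until = covered_until or length
        recs = []
        for res in range(1, length + 1):
            recs.append(ResidueContactRecord(
                "P1", res, 3.0 if res <= n_close else 50.0,
                LigandClass.DNA, structure_covered=res <= covered_until,
            ))
        return recs

    def test_more_than_three_contacts_positive(self):
        labels = label_binding_regions(self._region_set(),
                                       self._contacts(n_close=4))
        assert labels["P1:1"] is BindingLabel.POSITIVE

    def test_exactly_three_contacts_negative(self):
        labels = label_binding_regions(self._region_set(),
                                       self._contacts(n_close=3))
        assert labels["P1:1"] is BindingLabel.NEGATIVE

    def test_low_coverage_excluded(self):
        labels = label_binding_regions(self._region_set(),
                                       self._contacts(4, covered_until=70))
        assert labels["P1:1"] is BindingLabel.EXCLUDED

    def test_contact_tsv_round_trip(self, tmp_path):
        recs = self._contacts(4, length=10)
        path = tmp_path / "contacts.tsv"
        write_contact_tsv(recs, path)
        assert read_contact_tsv(path) == recs


class TestIdentityBaseline:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVL", "MKVL") == 1.0

    def test_nothing_in_common(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_single_substitution(self):
        assert pairwise_identity("ABCD", "ABED") == 0.75

    def test_max_over_positive_templates_only(self):
        templates = [("MKVL", 1), ("AAAA", 0), ("MKVV", 1)]
        assert identity_baseline("MKVL", templates) == 1.0
        with pytest.raises(ValueError):
            identity_baseline("MKVL", [("AAAA", 0)])


class TestCompareMethods:
    def _result(self, boots, seed=0, method="m"):
        return EvalResult("GO:1", method, float(np.median(boots)),
                          np.asarray(boots, dtype=float), seed)

    def test_identical_methods(self):
        boots = np.linspace(0.2, 0.8, 30)
        delta, p = compare_methods(self._result(boots), self._result(boots))
        assert (delta, p) == (0.0, 1.0)

    def test_constant_shift(self):
        boots = np.linspace(0.2, 0.8, 30)
        delta, _ = compare_methods(self._result(boots + 0.05),
                                   self._result(boots))
        assert delta == pytest.approx(0.05)

    def test_median_difference_matches_brute_force(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(101), rng.random(101)
        delta, _ = compare_methods(self._result(a), self._result(b))
        assert delta == pytest.approx(np.median(a) - np.median(b))

    def test_unpaired_inputs_rejected(self):
        boots = np.linspace(0.2, 0.8, 30)
        with pytest.raises(ValueError):
            compare_methods(self._result(boots, seed=0),
                            self._result(boots, seed=1))
        with pytest.raises(ValueError):
            compare_methods(self._result(boots), self._result(boots[:10]))


def test_blast_tabular_importer(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("q1\ts1\t97.5\t100\t2\t0\t1\t100\t1\t100\t1e-50\t200\n")
    df = ev.read_blast_tabular(path)
    assert df.loc[0, "pident"] == 97.5 and df.loc[0, "subject"] == "s1"
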
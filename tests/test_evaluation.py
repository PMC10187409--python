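import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vpfclass as v
from vpfclass import ValidationError
from conftest import brute_force_auroc, brute_force_best_f1


def _table(fams_per_cat, seqs_per_fam=3, cats=("x", "y")):
    p2f, f2c = {}, {}
    for cat in cats:
        for fi in range(fams_per_cat):
            fam = f"{cat}{fi}"
            f2c[fam] = cat
            for si in range(seqs_per_fam):
                p2f[f"{fam}_p{si}"] = fam
    return v.FamilyTable(p2f, f2c, v.CategorySet(cats))


class TestFamilyStratifiedKfold:
    def test_five_families_per_category_k5_forces_one_each(self):
        split = v.family_stratified_kfold(_table(5), k=5, seed=0)
        for fold in range(5):
            fams = split.fold_families(fold)
            cats = [f[0] for f in fams]
            assert sorted(cats) == ["x", "y"]

    def test_seven_families_spread_two_two_one_one_one(self):
        table = _table(7, cats=("x",))
        split = v.family_stratified_kfold(table, k=5, seed=3)
        counts = sorted(len(split.fold_families(f)) for f in range(5))
        assert counts == [1, 1, 1, 2, 2]

    def test_same_seed_reproduces_split(self):
        t = _table(6)
        a = v.family_stratified_kfold(t, k=3, seed=9)
        b = v.family_stratified_kfold(t, k=3, seed=9)
        assert a == b

    def test_category_with_too_few_families_named_in_error(self):
        with pytest.raises(ValidationError, match="'x' has only 4 families"):
            v.family_stratified_kfold(_table(4), k=5, seed=0)

    def test_folds_partition_all_families(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = _table(int(rng.integers(3, 9)), cats=("x", "y", "z"))
            k = int(rng.integers(2, 4))
            split = v.family_stratified_kfold(table, k=k, seed=seed)
            union = set()
            for fold in range(k):
                fams = set(split.fold_families(fold))
                assert not fams & union  # pairwise disjoint
                union |= fams
            assert union == set(table.families())
            # category balance within +-1
            for cat in ("x", "y", "z"):
                per_fold = [
                    sum(1 for f in split.fold_families(i) if f.startswith(cat))
                    for i in range(k)
                ]
                assert max(per_fold) - min(per_fold) <= 1


class TestSelectTestSequences:
    def test_single_member_family_is_forced(self):
        table = _table(2, seqs_per_fam=1)
        chosen = v.select_test_sequences(table, table.families(), seed=0)
        assert chosen == {f: f + "_p0" for f in table.families()}

    def test_selection_uniform_over_members(self):
        table = _table(1, seqs_per_fam=3, cats=("x",))
        counts = {m: 0 for m in table.members("x0")}
        n = 3000
        for seed in range(n):
            counts[v.select_test_sequences(table, ["x0"], seed=seed)["x0"]] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * se

    def test_same_seed_same_choice(self):
        table = _table(3, seqs_per_fam=5)
        a = v.select_test_sequences(table, table.families(), seed=4)
        b = v.select_test_sequences(table, table.families(), seed=4)
        assert a == b


class TestBinaryCurves:
    def test_perfect_ranking(self):
        assert v.binary_curves([0.9, 0.1], [1, 0]).auroc == 1.0

    def test_inverted_ranking(self):
        assert v.binary_curves([0.1, 0.9], [1, 0]).auroc == 0.0

    def test_interleaved_ranking(self):
        c = v.binary_curves([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0])
        assert c.auroc == pytest.approx(0.75, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            v.binary_curves([0.1, 0.9], [1, 1])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_auroc_matches_concordant_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = rng.choice(rng.random(max(2, n // 3)), size=n)  # with ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = v.binary_curves(scores, labels).auroc
        assert got == pytest.approx(brute_force_auroc(scores, labels), abs=1e-9)


class TestF1FromCounts:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(1, 0, 0, 1.0), (3, 1, 1, 0.75), (0, 5, 5, 0.0)]
    )
    def test_formula(self, tp, fp, fn, expected):
        assert v.f1_from_counts(tp, fp, fn) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_is_zero_with_warning(self, caplog):
        assert v.f1_from_counts(0, 0, 0) == 0.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(1, 9))
    @settings(deadline=None)
    def test_invariant_under_count_scaling(self, tp, fp, fn, c):
        if tp + fp + fn == 0:
            return
        assert v.f1_from_counts(c * tp, c * fp, c * fn) == pytest.approx(
            v.f1_from_counts(tp, fp, fn), abs=1e-12
        )


class TestOptimalF1Threshold:
    def test_perfect_pair(self):
        assert v.optimal_f1_threshold([0.9, 0.1], [1, 0]) == (0.9, 1.0)

    def test_exhaustive_three_point_example(self):
        thr, f1 = v.optimal_f1_threshold([0.9, 0.8, 0.3], [1, 0, 1])
        assert (thr, f1) == (0.3, pytest.approx(0.8, abs=1e-12))

    def test_all_positive_gives_min_score(self):
        thr, f1 = v.optimal_f1_threshold([0.5, 0.2, 0.8], [1, 1, 1])
        assert thr == 0.2 and f1 == 1.0

    def test_no_positive_rejected(self):
        with pytest.raises(ValidationError):
            v.optimal_f1_threshold([0.5], [0])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 500))
        scores = rng.choice(rng.random(max(2, n // 4)), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        got_t, got_f1 = v.optimal_f1_threshold(scores, labels)
        exp_t, exp_f1 = brute_force_best_f1(scores, labels)
        assert got_f1 == pytest.approx(exp_f1, abs=1e-12)
        assert got_t == exp_t  # ties break toward the larger threshold in both


class TestWeightedF1:
    @pytest.mark.parametrize(
        "f1,support,expected",
        [([1.0, 0.0], [1, 1], 0.5), ([1.0, 0.5], [3, 1], 0.875), ([0.42], [7], 0.42)],
    )
    def test_support_weighting(self, f1, support, expected):
        assert v.weighted_f1(f1, support) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            v.weighted_f1([1.0], [1, 2])


class TestCrossvalRun:
    @pytest.fixture(scope="class")
    def small_result(self):
        cfg = v.SyntheticConfig(
            n_categories=3, families_per_category=5, sequences_per_family=4,
            dim=8, category_separation=8.0, seed=21,
        )
        table, emb = v.generate_embedding_fixture(cfg)
        return table, v.crossval_run(emb, table, k=5, seed=21)

    def test_each_family_tested_exactly_once(self, small_result):
        table, result = small_result
        tested = [f for r in result.reports for f in r.test_families]
        assert sorted(tested) == table.families()

    def test_no_family_leaks_between_train_and_test(self, small_result):
        table, result = small_result
        split = result.split
        for r in result.reports:
            test_fams = set(r.test_families)
            train_fams = {
                f for f, i in split.family_to_fold.items() if i != r.fold
            }
            assert not test_fams & train_fams
            for fam in test_fams:
                assert split.test_protein[fam] in table.members(fam)

    def test_separable_fixture_scores_high(self, small_result):
        _, result = small_result
        assert result.mean_auroc > 0.9


class TestMakeBinaryTask:
    def test_union_arithmetic(self):
        sets = [
            v.LabeledSet("capsid", "train", tuple(f"c{i}" for i in range(10))),
            v.LabeledSet("tail", "train", tuple(f"t{i}" for i in range(5))),
            v.LabeledSet("other", "train", tuple(f"o{i}" for i in range(20))),
        ]
        task = v.make_binary_task(sets, ["capsid", "tail"])
        assert task.n_positive == 15 and task.n_negative == 20

    def test_roles_preserved(self):
        sets = [
            v.LabeledSet("pvp", "train", ("a", "b")),
            v.LabeledSet("pvp", "test", ("c",)),
            v.LabeledSet("neg", "test", ("d",)),
        ]
        task = v.make_binary_task(sets, ["pvp"])
        assert task.train_ids == ("a", "b")
        assert task.test_ids == ("c", "d")
        assert task.test_labels == (1, 0)

    def test_empty_positive_rejected(self):
        with pytest.raises(ValidationError):
            v.make_binary_task([v.LabeledSet("neg", "train", ("a",))], ["pos"])

    def test_train_test_overlap_rejected(self):
        sets = [
            v.LabeledSet("pvp", "train", ("a",)),
            v.LabeledSet("neg", "test", ("a",)),
        ]
        with pytest.raises(ValidationError):
            v.make_binary_task(sets, ["pvp"])
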
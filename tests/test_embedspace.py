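import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vpfclass as v
from vpfclass import ValidationError


def _table_from(fam_to_cat, members_per_fam=1):
    p2f = {}
    for fam in fam_to_cat:
        for i in range(members_per_fam):
            p2f[f"{fam}_p{i}"] = fam
    cats = tuple(sorted(set(fam_to_cat.values())))
    return v.FamilyTable(p2f, dict(fam_to_cat), v.CategorySet(cats))


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "u,w,expected",
        [
            ((1, 0), (1, 0), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 1), (1, 0), 1 / np.sqrt(2)),
        ],
    )
    def test_closed_forms(self, u, w, expected):
        assert v.cosine_similarity(u, w) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            v.cosine_similarity((0, 0), (1, 0))

    @given(st.floats(1e-3, 1e3), st.integers(0, 1000))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        u, w = rng.standard_normal((2, 5))
        assert v.cosine_similarity(c * u, w) == pytest.approx(
            v.cosine_similarity(u, w), abs=1e-9
        )


class TestFamilyCentroids:
    def test_identical_rows_give_that_row(self):
        table = _table_from({"f1": "a", "f2": "a"}, members_per_fam=2)
        x = np.tile([1.0, 2.0], (4, 1))
        emb = v.EmbeddingMatrix(sorted(table.protein_to_family), x)
        cents = {c.family_id: c.vector for c in v.family_centroids(emb, table)}
        assert np.allclose(cents["f1"], [1, 2])

    def test_elementwise_mean(self):
        table = _table_from({"f1": "a"}, members_per_fam=3)
        emb = v.EmbeddingMatrix(
            table.members("f1"), np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 1.0]])
        )
        (cent,) = v.family_centroids(emb, table)
        assert np.allclose(cent.vector, [2.0, 1.0], atol=1e-12)
        assert cent.n_members == 3

    def test_family_without_embeddings_rejected(self):
        table = _table_from({"f1": "a", "f2": "a"})
        emb = v.EmbeddingMatrix(["f1_p0"], np.ones((1, 2)))
        with pytest.raises(ValidationError, match="f2"):
            v.family_centroids(emb, table)


class TestIntraFamilySimilarity:
    def test_pair_of_identical_vectors(self):
        table = _table_from({"f1": "a"}, members_per_fam=2)
        emb = v.EmbeddingMatrix(table.members("f1"), np.tile([1.0, 1.0], (2, 1)))
        assert v.intra_family_similarity(emb, table)["f1"] == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        table = _table_from({"f1": "a"}, members_per_fam=2)
        emb = v.EmbeddingMatrix(table.members("f1"), np.array([[1.0, 0], [0, 1.0]]))
        assert v.intra_family_similarity(emb, table)["f1"] == pytest.approx(0.0)

    def test_three_member_hand_computation(self):
        table = _table_from({"f1": "a"}, members_per_fam=3)
        emb = v.EmbeddingMatrix(
            table.members("f1"), np.array([[1.0, 0], [0, 1.0], [1.0, 1.0]])
        )
        expected = (0 + 1 / np.sqrt(2) + 1 / np.sqrt(2)) / 3
        assert v.intra_family_similarity(emb, table)["f1"] == pytest.approx(
            expected, abs=1e-9
        )

    def test_singletons_skipped(self):
        table = _table_from({"f1": "a"}, members_per_fam=1)
        emb = v.EmbeddingMatrix(table.members("f1"), np.ones((1, 2)))
        assert v.intra_family_similarity(emb, table) == {}


class TestExcludeNearDuplicates:
    def test_above_cutoff_excluded(self):
        assert "f" not in v.exclude_near_duplicate_families({"f": 0.9995})

    def test_boundary_retained(self):
        assert "f" in v.exclude_near_duplicate_families({"f": 0.999})

    def test_empty_input(self):
        assert v.exclude_near_duplicate_families({}) == {}


class TestCategorySimilarityMatrix:
    def test_single_family_categories_off_diagonal(self):
        table = _table_from({"f1": "a", "f2": "b"})
        cents = [
            v.FamilyCentroid("f1", np.array([1.0, 0.0]), 1),
            v.FamilyCentroid("f2", np.array([0.0, 1.0]), 1),
        ]
        m = v.category_similarity_matrix(cents, table)
        assert m.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m.matrix[0, 0])  # diagonal undefined for 1 family

    def test_two_pair_mean(self):
        table = _table_from({"f1": "a", "f2": "a", "f3": "b"})
        cents = [
            v.FamilyCentroid("f1", np.array([1.0, 0.0]), 1),
            v.FamilyCentroid("f2", np.array([0.0, 1.0]), 1),
            v.FamilyCentroid("f3", np.array([1.0, 1.0]), 1),
        ]
        m = v.category_similarity_matrix(cents, table)
        assert m.matrix[0, 1] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)
        assert m.matrix[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        fams = {f"f{i}": ("a", "b", "c")[i % 3] for i in range(18)}
        table = _table_from(fams)
        vectors = {f: rng.standard_normal(6) for f in fams}
        cents = [v.FamilyCentroid(f, vec, 1) for f, vec in vectors.items()]
        m = v.category_similarity_matrix(cents, table)
        by_cat = table.families_by_category()
        for i, a in enumerate(m.categories):
            for j, b in enumerate(m.categories):
                if i == j:
                    pairs = [
                        v.cosine_similarity(vectors[x], vectors[y])
                        for x, y in itertools.combinations(by_cat[a], 2)
                    ]
                else:
                    pairs = [
                        v.cosine_similarity(vectors[x], vectors[y])
                        for x in by_cat[a]
                        for y in by_cat[b]
                    ]
                assert m.matrix[i, j] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        fams = {f"f{i}": ("a", "b")[i % 2] for i in range(8)}
        table = _table_from(fams)
        cents = [v.FamilyCentroid(f, rng.standard_normal(4), 1) for f in fams]
        m = v.category_similarity_matrix(cents, table)
        assert np.allclose(m.matrix, m.matrix.T, equal_nan=True)


def _block_matrix(names, blocks, within=0.9, between=0.1):
    n = len(names)
    m = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if blocks[i] == blocks[j]:
                m[i, j] = within
    np.fill_diagonal(m, 1.0)
    return v.CategorySimilarityMatrix(tuple(names), m)


class TestSpectralBipartition:
    def test_recovers_two_blocks_of_two(self):
        m = _block_matrix(("c1", "c2", "c3", "c4"), [0, 0, 1, 1])
        part = v.spectral_bipartition(m, seed=0)
        assert part["c1"] == part["c2"] != part["c3"] == part["c4"]

    def test_agrees_with_exhaustive_ncut_oracle(self):
        m = _block_matrix(tuple(f"c{i}" for i in range(7)), [0, 0, 0, 1, 1, 1, 1])
        part = v.spectral_bipartition(m, seed=0)
        got = np.array([part[c] for c in m.categories])
        oracle = v.min_ncut_bipartition(m.matrix)
        assert np.array_equal(got, oracle) or np.array_equal(got, 1 - oracle)

    def test_two_categories_trivial_split(self):
        m = _block_matrix(("a", "b"), [0, 1])
        assert sorted(v.spectral_bipartition(m).values()) == [0, 1]

    def test_constant_matrix_flagged_degenerate(self, caplog):
        n = 5
        mat = np.full((n, n), 0.5)
        m = v.CategorySimilarityMatrix(tuple(f"c{i}" for i in range(n)), mat)
        with caplog.at_level("WARNING"):
            part = v.spectral_bipartition(m, seed=1)
        assert "degenerate" in caplog.text
        assert set(part.values()) == {0, 1}

    def test_negative_entries_shifted_to_affinities(self):
        m = _block_matrix(("a", "b", "c", "d"), [0, 0, 1, 1],
                          within=0.8, between=-0.5)
        part = v.spectral_bipartition(m, seed=0)
        assert part["a"] == part["b"] != part["c"] == part["d"]


class TestRandomBipartitions:
    def test_requested_count_and_nonempty_groups(self):
        splits = v.random_category_bipartitions(
            [f"c{i}" for i in range(9)], n_splits=10, seed=0
        )
        assert len(splits) == 10
        for s in splits:
            assert set(s.values()) == {0, 1}

    def test_two_categories_only_split(self):
        for s in v.random_category_bipartitions(["a", "b"], 5, seed=2):
            assert sorted(s.values()) == [0, 1]

    def test_reproducible_from_seed(self):
        a = v.random_category_bipartitions(list("abcde"), 10, seed=3)
        b = v.random_category_bipartitions(list("abcde"), 10, seed=3)
        assert a == b


class TestRelabelByPartition:
    def test_nine_to_two_categories(self):
        fams = {f"f{i}": f"cat{i}" for i in range(9)}
        table = _table_from(fams)
        partition = {f"cat{i}": int(i >= 4) for i in range(9)}
        out = v.relabel_families_by_partition(table, partition)
        assert out.category_set.names == ("cluster1", "cluster2")
        assert out.category_of("f0") == "cluster1"
        assert out.category_of("f8") == "cluster2"
        assert out.protein_to_family == table.protein_to_family

    def test_missing_category_rejected(self):
        table = _table_from({"f1": "a", "f2": "b"})
        with pytest.raises(ValidationError):
            v.relabel_families_by_partition(table, {"a": 0})
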
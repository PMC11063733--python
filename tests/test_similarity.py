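import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scplpa.core_io import AssociationMatrix, DiseaseDAGSet
from scplpa.similarity import (
    ancestor_contribution,
    disease_semantic_similarity,
    gip_pair,
    gip_similarity,
    integrate_disease,
    integrate_mirna,
    mirna_functional_similarity,
    semantic_value,
    set_association,
)
from scplpa.core_io import SimilarityMatrix
from scplpa.synthetic_data import FixtureSpec, generate_fixture

# ---------------------------------------------------------------------------
# independent oracles: plain-python nested loops over the defining formulas
# ---------------------------------------------------------------------------


def oracle_contributions(dag_set):
    n = dag_set.universe_size
    terms = set().union(*dag_set.ancestors.values())
    return {
        t: -math.log(sum(t in anc for anc in dag_set.ancestors.values()) / n)
        for t in terms
    }


def oracle_semantic_matrix(dag_set):
    contrib = oracle_contributions(dag_set)
    dv = {d: sum(contrib[t] for t in anc) for d, anc in dag_set.ancestors.items()}
    ds = dag_set.diseases
    out = np.zeros((len(ds), len(ds)))
    for i, di in enumerate(ds):
        for j, dj in enumerate(ds):
            denom = dv[di] + dv[dj]
            if denom <= 0:
                continue
            shared = dag_set.ancestors[di] & dag_set.ancestors[dj]
            out[i, j] = sum(contrib[t] + contrib[t] for t in shared) / denom
    return out


def oracle_functional_matrix(md, dd):
    nm = md.shape[0]
    out = np.zeros((nm, nm))
    sets = [list(np.flatnonzero(md[i] == 1)) for i in range(nm)]
    for i in range(nm):
        for j in range(nm):
            if i == j:
                out[i, j] = 1.0
                continue
            di, dj = sets[i], sets[j]
            if not di or not dj:
                continue
            total = sum(max(dd[d, t] for t in dj) for d in di)
            total += sum(max(dd[d, t] for t in di) for d in dj)
            out[i, j] = total / (len(di) + len(dj))
    return out


# ---------------------------------------------------------------------------
# ancestor contributions and semantic values
# ---------------------------------------------------------------------------


class TestContributions:
    def test_universal_term_contributes_zero(self):
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "R")])
        table = ancestor_contribution(dags)
        assert table.contributions["R"] == pytest.approx(0.0)

    def test_unique_term_contributes_log_n(self):
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "R"), ("C", "R")])
        table = ancestor_contribution(dags)
        assert table.contributions["A"] == pytest.approx(math.log(4))

    def test_half_frequency_term_is_log_two(self):
        # term R appears in 2 of 4 disease DAGs
        dags = DiseaseDAGSet.from_edges(
            [("A", "R"), ("B", "R"), ("C", "S"), ("D", "S")],
            diseases=["A", "B", "C", "D"],
        )
        table = ancestor_contribution(dags)
        assert table.contributions["R"] == pytest.approx(-math.log(2 / 4))

    def test_log_base_rescales(self):
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "S")], diseases=["A", "B"])
        nat = ancestor_contribution(dags)
        b2 = ancestor_contribution(dags, log_base=2)
        assert b2.contributions["R"] == pytest.approx(nat.contributions["R"] / math.log(2))

    def test_semantic_value_single_term_dag(self):
        dags = DiseaseDAGSet.from_edges([("A", "R")], diseases=["A", "R"])
        table = ancestor_contribution(dags)
        # R's DAG is just {R}; R appears in both DAGs so contributes 0
        assert semantic_value("R", table) == pytest.approx(0.0)

    def test_semantic_value_matches_explicit_sum(self):
        dags = DiseaseDAGSet.from_edges(
            [("A", "B"), ("B", "R"), ("C", "R")], diseases=["A", "C"]
        )
        table = ancestor_contribution(dags)
        oracle = oracle_contributions(dags)
        expected = sum(oracle[t] for t in dags.ancestors["A"])
        assert semantic_value("A", table) == pytest.approx(expected)

    def test_unknown_disease_rejected(self):
        table = ancestor_contribution(DiseaseDAGSet.from_edges([("A", "R")]))
        with pytest.raises(KeyError):
            semantic_value("nope", table)


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self):
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "S")], diseases=["A", "B"])
        dd = disease_semantic_similarity(dags)
        assert dd.values[0, 0] == pytest.approx(1.0)

    def test_disjoint_ancestors_similarity_zero(self):
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "S")], diseases=["A", "B"])
        dd = disease_semantic_similarity(dags)
        assert dd.values[0, 1] == 0.0

    def test_three_disease_forest_matches_oracle(self):
        # A->R, B->R chains plus standalone C; universe of 3 diseases
        dags = DiseaseDAGSet.from_edges(
            [("A", "R"), ("B", "R"), ("C", "S")], diseases=["A", "B", "C"]
        )
        dd = disease_semantic_similarity(dags)
        np.testing.assert_allclose(dd.values, oracle_semantic_matrix(dags), atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_forests_match_oracle(self, seed):
        spec = FixtureSpec(nm=4, nd=np.random.default_rng(seed).integers(3, 11),
                           n_blocks=2, seed=seed)
        _, dags = generate_fixture(spec)
        dd = disease_semantic_similarity(dags)
        np.testing.assert_allclose(dd.values, oracle_semantic_matrix(dags), atol=1e-12)


class TestSetAssociation:
    def _dd(self):
        vals = np.array([[1.0, 0.3, 0.7], [0.3, 1.0, 0.2], [0.7, 0.2, 1.0]])
        return SimilarityMatrix(vals, ("d0", "d1", "d2"))

    def test_member_of_set_gives_one(self):
        assert set_association("d0", ["d0", "d1"], self._dd()) == 1.0

    def test_zero_similarities_give_zero(self):
        dd = SimilarityMatrix(np.eye(3), ("d0", "d1", "d2"))
        assert set_association("d0", ["d1", "d2"], dd) == 0.0

    def test_max_over_set(self):
        assert set_association("d0", ["d1", "d2"], self._dd()) == pytest.approx(0.7)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            set_association("d0", [], self._dd())


class TestFunctionalSimilarity:
    def test_self_similarity_one(self, two_block_assoc, two_block_dags):
        dd = disease_semantic_similarity(two_block_dags)
        mm = mirna_functional_similarity(two_block_assoc, dd)
        np.testing.assert_allclose(np.diag(mm.values), 1.0)

    def test_unrelated_disease_sets_give_zero(self):
        md = np.array([[1.0, 0], [0, 1]])
        assoc = AssociationMatrix(md, ("m1", "m2"), ("A", "B"))
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "S")], diseases=["A", "B"])
        mm = mirna_functional_similarity(assoc, disease_semantic_similarity(dags))
        assert mm.values[0, 1] == 0.0

    def test_empty_disease_set_row_is_zero_except_diagonal(self):
        md = np.array([[1.0, 1], [0, 0]])
        assoc = AssociationMatrix(md, ("m1", "m2"), ("A", "B"))
        dags = DiseaseDAGSet.from_edges([("A", "R"), ("B", "R")], diseases=["A", "B"])
        mm = mirna_functional_similarity(assoc, disease_semantic_similarity(dags))
        assert mm.values[1, 0] == 0.0 and mm.values[1, 1] == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_exhaustive_oracle(self, seed):
        spec = FixtureSpec(nm=int(np.random.default_rng(seed).integers(2, 9)),
                           nd=6, n_blocks=2, seed=seed)
        assoc, dags = generate_fixture(spec)
        dd = disease_semantic_similarity(dags)
        mm = mirna_functional_similarity(assoc, dd)
        np.testing.assert_allclose(
            mm.values, oracle_functional_matrix(assoc.values, dd.values), atol=1e-12
        )


class TestGIP:
    def test_identical_profiles_similarity_one(self):
        sim, _ = gip_similarity(np.array([[1.0, 0], [1, 0]]), ("a", "b"))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal(self):
        sim, _ = gip_similarity(np.array([[1.0, 0], [0, 1], [1, 1]]), ("a", "b", "c"))
        np.testing.assert_allclose(np.diag(sim.values), 1.0)

    def test_orthogonal_profiles_closed_form(self):
        # norms 1 each -> gamma = 1; squared distance 2 -> K = exp(-2)
        sim, gamma = gip_similarity(np.array([[1.0, 0], [0, 1]]), ("a", "b"))
        assert gamma == pytest.approx(1.0)
        assert sim.values[0, 1] == pytest.approx(math.exp(-2))

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gip_similarity(np.zeros((3, 4)), ("a", "b", "c"))

    def test_pair_uses_columns_for_diseases_rows_for_mirnas(self, two_block_assoc):
        gd, gm, params = gip_pair(two_block_assoc)
        assert gd.values.shape == (3, 3) and gm.values.shape == (3, 3)
        md = two_block_assoc.values
        assert params.gamma_d == pytest.approx(1.0 / (md.T**2).sum(1).mean())
        assert params.gamma_m == pytest.approx(1.0 / (md**2).sum(1).mean())

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((5, 4)) < 0.5).astype(float)
        profiles[0, 0] = 1.0  # keep at least one nonzero profile
        names = tuple("abcde")
        sim, _ = gip_similarity(profiles, names)
        perm = rng.permutation(5)
        sim_p, _ = gip_similarity(profiles[perm], tuple(names[i] for i in perm))
        np.testing.assert_allclose(sim_p.values, sim.values[np.ix_(perm, perm)], atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_unit_similarity_iff_identical_profiles(self, seed):
        rng = np.random.default_rng(seed)
        profiles = (rng.random((6, 5)) < 0.4).astype(float)
        profiles[0, 0] = 1.0
        sim, _ = gip_similarity(profiles, tuple("abcdef"))
        for i in range(6):
            for j in range(6):
                same = np.array_equal(profiles[i], profiles[j])
                assert (sim.values[i, j] == pytest.approx(1.0)) == same


class TestIntegration:
    def _pair(self, a, b):
        names = tuple(f"x{i}" for i in range(a.shape[0]))
        return (SimilarityMatrix(a, names, "semantic"), SimilarityMatrix(b, names, "gip"))

    def test_disease_average_of_equal_is_identity(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        dd, gd = self._pair(a, a.copy())
        np.testing.assert_allclose(integrate_disease(dd, gd).values, a)

    def test_disease_elementwise_mean(self):
        dd, gd = self._pair(np.array([[1.0, 0.0], [0.0, 1.0]]),
                            np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert integrate_disease(dd, gd).values[0, 1] == pytest.approx(0.2)

    def test_mirna_keeps_functional_where_nonzero(self):
        mm, gm = self._pair(np.array([[1.0, 0.5], [0.5, 1.0]]),
                            np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert integrate_mirna(mm, gm).values[0, 1] == pytest.approx(0.5)

    def test_mirna_falls_back_to_gip_where_zero(self):
        mm, gm = self._pair(np.eye(2), np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert integrate_mirna(mm, gm).values[0, 1] == pytest.approx(0.9)

    def test_shape_mismatch_rejected(self):
        a = SimilarityMatrix(np.eye(2), ("x0", "x1"), "semantic")
        b = SimilarityMatrix(np.eye(3), ("x0", "x1", "x2"), "gip")
        with pytest.raises(ValueError):
            integrate_disease(a, b)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_integrated_outputs_stay_valid_similarities(self, seed):
        """Symmetry, unit diagonal and [0,1] range survive integration."""
        rng = np.random.default_rng(seed)
        spec = FixtureSpec(nm=5, nd=4, n_blocks=2, seed=int(rng.integers(0, 2**16)))
        assoc, dags = generate_fixture(spec)
        dd = disease_semantic_similarity(dags)
        mm = mirna_functional_similarity(assoc, dd)
        gd, gm, _ = gip_pair(assoc)
        for sim in (integrate_disease(dd, gd), integrate_mirna(mm, gm)):
            sim.validate()
            np.testing.assert_allclose(np.diag(sim.values), 1.0)
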
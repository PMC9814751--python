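"""Prioritization: greedy cover selection, random and GP-uncertainty baselines."""

import numpy as np
import pytest

from solucover.selector import (Ranking, SelectionState, SFMParams,
                                coverage_curve, rank_random, rank_sfmmol,
                                rank_unc, sfmmol_score)
from solucover.simgraph import Fingerprint, MolecularSpace
from solucover.synthdata import SpaceSpec, synth_space

from conftest import path_graph_space, random_space, star_graph_space


def greedy_oracle(space, n_select, lam=1.0):
    """Exhaustive greedy reference: brute-force score over the distance
    matrix, independent of the vectorized implementation."""
    D = np.asarray(space.distances, dtype=float)
    n = space.nmol
    evaluated, covered = [], set()
    order, scores = [], []
    for _ in range(n_select):
        best_score, best_i = -np.inf, None
        for i in range(n):
            if i in evaluated:
                continue
            nbrs = {j for j in range(n) if D[i, j] < space.d_th}
            reward = sum(space.weights[j] for j in nbrs - covered)
            penalty = len(nbrs & set(evaluated))
            s = reward - lam * space.w_tot * penalty
            if s > best_score + 1e-9:
                best_score, best_i = s, i
        order.append(best_i)
        scores.append(best_score)
        evaluated.append(best_i)
        covered |= {j for j in range(n) if D[best_i, j] < space.d_th}
    return order, scores


class TestSfmmolScore:
    def test_first_pick_scores_total_neighbor_count(self):
        sp = star_graph_space(4)
        state = SelectionState(nmol=sp.nmol)
        params = SFMParams(d_th=sp.d_th, n_select=2)
        # hub neighbors: itself + 4 leaves
        assert sfmmol_score(sp, state, 0, params) == 5.0
        # each leaf: itself + hub
        assert sfmmol_score(sp, state, 1, params) == 2.0

    def test_isolated_candidate_scores_one(self):
        sp = path_graph_space(6)
        sp2 = MolecularSpace(sp.fingerprints, d_th=sp.d_th)
        sp2._distances = sp.distances.copy()
        sp2._distances[5, :] = sp2._distances[:, 5] = 1.0
        sp2._distances[5, 5] = 0.0
        state = SelectionState(nmol=6)
        assert sfmmol_score(sp2, state, 5, SFMParams(d_th=sp.d_th, n_select=1)) == 1.0

    def test_penalty_magnitude_is_nmol_per_evaluated_neighbor(self):
        # candidate with 1 evaluated neighbor and 3 uncovered neighbors in a
        # 100-molecule space scores 3 - 100*1 = -97
        n = 100
        D = np.ones((n, n))
        np.fill_diagonal(D, 0.0)
        cand, ev = 0, 1
        for j in (1, 2, 3, 4):
            D[cand, j] = D[j, cand] = 0.1
        from conftest import space_from_distances
        sp = space_from_distances(D, d_th=0.3)
        # the evaluated molecule's neighborhood is covered: itself and cand
        state = SelectionState(nmol=n, evaluated=[ev],
                               covered={j for j in range(n) if D[ev, j] < 0.3})
        assert state.covered == {0, 1}
        score = sfmmol_score(sp, state, cand, SFMParams(d_th=0.3, n_select=2))
        assert score == 3 - n * 1


class TestRankSfmmol:
    def test_hub_picked_first(self):
        sp = star_graph_space(5)
        ranking = rank_sfmmol(sp, SFMParams(d_th=sp.d_th, n_select=3))
        assert ranking.indices[0] == 0
        assert ranking.scores[0] == 6.0

    def test_star_second_pick_ties_break_to_lowest_index(self):
        sp = star_graph_space(5)
        ranking = rank_sfmmol(sp, SFMParams(d_th=sp.d_th, n_select=2))
        # every leaf is covered and adjacent to the evaluated hub: all tie
        # at score -NMOL, so the tie rule picks the lowest index
        assert ranking.indices[1] == 1
        assert ranking.scores[1] == -float(sp.nmol)

    def test_matches_exhaustive_oracle_on_random_spaces(self, rng):
        for _ in range(15):
            sp = random_space(rng, n_max=40)
            k = min(6, sp.nmol)
            ranking = rank_sfmmol(sp, SFMParams(d_th=sp.d_th, n_select=k,
                                                tie_rule="index"))
            oracle_order, oracle_scores = greedy_oracle(sp, k)
            assert ranking.indices == oracle_order
            assert np.allclose(ranking.scores, oracle_scores)

    def test_evaluated_neighbor_never_outranks_fresh_region(self, rng):
        # with lam=1 the penalty (NMOL per evaluated neighbor) dominates any
        # reward, which is < NMOL
        for _ in range(10):
            sp = random_space(rng, n_max=40)
            ranking = rank_sfmmol(sp, SFMParams(d_th=sp.d_th,
                                                n_select=min(8, sp.nmol)))
            A = sp.adjacency
            evaluated = []
            for step, pick in enumerate(ranking.indices):
                if evaluated:
                    uncovered = ~A[evaluated].any(axis=0)
                    fresh = [i for i in range(sp.nmol)
                             if i not in evaluated
                             and not A[i][evaluated].any()
                             and (A[i] & uncovered).any()]
                    if fresh:
                        assert not A[pick][evaluated].any()
                evaluated.append(pick)

    def test_n_select_truncated_with_warning(self):
        sp = path_graph_space(4)
        with pytest.warns(UserWarning, match="truncat"):
            ranking = rank_sfmmol(sp, SFMParams(d_th=sp.d_th, n_select=99))
        assert len(ranking) == 4
        assert sorted(ranking.indices) == [0, 1, 2, 3]


class TestRankRandom:
    def test_reproducible_per_seed(self):
        sp = path_graph_space(8)
        a = rank_random(sp, 5, seed=7)
        b = rank_random(sp, 5, seed=7)
        assert a.indices == b.indices
        assert rank_random(sp, 5, seed=8).indices != a.indices

    def test_full_permutation(self):
        sp = path_graph_space(7)
        r = rank_random(sp, 7, seed=0)
        assert sorted(r.indices) == list(range(7))

    def test_first_pick_uniform_over_seeds(self):
        sp = path_graph_space(10)
        firsts = np.array([rank_random(sp, 1, seed=s).indices[0]
                           for s in range(1000)])
        counts = np.bincount(firsts, minlength=10)
        # binomial(1000, 0.1): mean 100, sd ~9.5; allow 5 sigma
        assert np.all(np.abs(counts - 100) < 48)


class TestRankUnc:
    def _two_cluster_space(self):
        fps = []
        for base in (0, 50):
            for off in range(3):
                bits = set(range(base, base + 10))
                bits.discard(base + off)  # slight within-cluster variation
                fps.append(Fingerprint(frozenset(bits), nbits=64))
        return MolecularSpace(fps, d_th=0.3)

    def test_first_two_picks_span_both_clusters(self):
        sp = self._two_cluster_space()
        r = rank_unc(sp, 4)
        first_cluster = r.indices[0] // 3
        assert r.indices[1] // 3 == 1 - first_cluster

    def test_variance_matches_closed_form(self):
        sp = self._two_cluster_space()
        r = rank_unc(sp, 6, jitter=1e-6)
        K = 1.0 - np.asarray(sp.distances, dtype=float)
        for step in range(1, 6):
            E = r.indices[:step]
            KEE = K[np.ix_(E, E)] + 1e-6 * np.eye(step)
            for cand, score in [(r.indices[step], r.scores[step])]:
                kxE = K[E, cand]
                var = K[cand, cand] + 1e-6 - kxE @ np.linalg.solve(KEE, kxE)
                assert score == pytest.approx(var, abs=1e-8)

    def test_duplicate_of_evaluated_never_picked_while_others_remain(self):
        bits = [frozenset(range(10)), frozenset(range(10)),  # exact duplicates
                frozenset(range(20, 30)), frozenset(range(40, 50))]
        sp = MolecularSpace([Fingerprint(b, 64) for b in bits], d_th=0.3)
        r = rank_unc(sp, 4)
        dup = {0, 1}
        # the twin of an evaluated molecule has posterior variance ~0, so the
        # two duplicates are never chosen back to back
        first_dup = min(i for i, idx in enumerate(r.indices) if idx in dup)
        assert r.indices[first_dup + 1] not in dup

    def test_isolated_candidate_has_prior_variance_and_early_pick(self):
        bits = [frozenset(range(10)), frozenset(range(8)),
                frozenset(range(9)), frozenset(range(50, 60))]
        sp = MolecularSpace([Fingerprint(b, 64) for b in bits], d_th=0.3)
        r = rank_unc(sp, 4)
        assert r.indices[0] == 3  # largest summed distance
        assert r.scores[0] == pytest.approx(1.0)

    def test_degenerate_identical_space_rejected(self):
        fps = [Fingerprint(frozenset(range(10)), 64)] * 4
        sp = MolecularSpace(fps, d_th=0.3)
        with pytest.raises(ValueError, match="identical"):
            rank_unc(sp, 2)

    def test_deterministic_and_response_free(self):
        # posterior variance depends only on the evaluated inputs, so two
        # runs (there is no response to vary) must agree exactly
        sp = self._two_cluster_space()
        assert rank_unc(sp, 5).indices == rank_unc(sp, 5).indices


class TestCoverageCurve:
    def test_prefix_zero_and_full(self):
        sp = path_graph_space(6)
        full = rank_random(sp, 6, seed=0)
        curve = coverage_curve(sp, full, order=1)
        assert curve[0] == (0, 0.0)
        assert curve[-1] == (6, 1.0)
        vals = [c for _, c in curve]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_toy_path_graph_hand_computed(self):
        sp = path_graph_space(6)
        ranking = Ranking(order=["0", "3"], indices=[0, 3],
                          scores=[0.0, 0.0], algorithm="random")
        c1 = coverage_curve(sp, ranking, order=1)
        assert c1 == [(0, 0.0), (1, pytest.approx(2 / 6)), (2, pytest.approx(5 / 6))]
        c2 = coverage_curve(sp, ranking, order=2)
        assert c2 == [(0, 0.0), (1, pytest.approx(3 / 6)), (2, pytest.approx(1.0))]

    def test_sfmmol_beats_random_on_clustered_space(self):
        space, _ = synth_space(SpaceSpec(n_molecules=200, n_clusters=8, seed=3))
        sfm = rank_sfmmol(space, SFMParams(d_th=space.d_th, n_select=8))
        cov_sfm = space.coverage(sfm.indices, order=2)
        cov_rand = np.mean([space.coverage(rank_random(space, 8, seed=s).indices,
                                           order=2) for s in range(30)])
        assert cov_sfm > cov_rand
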